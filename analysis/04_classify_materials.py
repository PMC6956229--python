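#!/usr/bin/env python
"""Classify every material's roll compaction behavior (RCBCS).

Category I: the ribbon quality target (0.6 <= SF <= 0.8, TS >= 1 MPa) is
reached at some pressure; Category II: only over-densified strong
ribbons (SF > 0.8, TS >= 1 MPa); Category III: TS < 1 MPa everywhere.
Subcategory A/B marks whether the criterion is met at 30-70 bar or only
at 90-110 bar. Also writes the TS-SF map (with target-region flags) and
a chart of it.
"""

import argparse
from pathlib import Path

import pandas as pd

from rollcompact import metrology, rcbcs, viz


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    samples = metrology.read_ribbon_table(args.out / "ribbon_measurements.csv")
    profiles = metrology.profiles_from_table(samples)
    labels = rcbcs.classify_all(profiles)
    rcbcs.label_table(labels).to_csv(args.out / "rcbcs_labels.csv", index=False)

    desc = pd.read_csv(args.out / "descriptors.csv")
    types = dict(zip(desc.material_id, desc.type))
    by_mat = {}
    for s in samples:
        by_mat.setdefault(s.material_id, []).append(s)
    summary = rcbcs.category_summary(labels, types, by_mat)
    summary.to_csv(args.out / "category_summary.csv", float_format="%.6g")

    ts_sf = rcbcs.ts_sf_map(profiles)
    ts_sf.to_csv(args.out / "ts_sf_map.csv", index=False, float_format="%.6g")
    viz.plot_ts_sf_map(ts_sf, args.out / "ts_sf_map.png")

    print("category contingency (rows: subcategory):")
    print(summary.to_string())
    mains = pd.read_csv(args.out / "rcbcs_labels.csv").main.value_counts().to_dict()
    print("main categories:", mains)
    print("transversal-splitting rates by category:",
          summary["transversal_rate"].round(3).to_dict())


if __name__ == "__main__":
    main()
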