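#!/usr/bin/env python
"""Fit the strength-porosity and strength-pressure models per material.

The Ryshkewitch-Duckworth law TS = TS0 exp(-kb eps) is fitted as a line
in (porosity, ln TS); the power law TS = d P^g by Levenberg-Marquardt.
Each fit is screened for applicability (>= 3 points, R^2 >= 0.7,
plausible TS0), mirroring the screening that reduces the library to the
modellable subset.
"""

import argparse
from pathlib import Path

from rollcompact import metrology, models


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    samples = metrology.read_ribbon_table(args.out / "ribbon_measurements.csv")
    profiles = metrology.profiles_from_table(samples)
    fits = models.fit_table(profiles)
    fits.to_csv(args.out / "compaction_fits.csv", index=False, float_format="%.6g")
    fits.to_json(args.out / "compaction_fits.json", orient="records", indent=1)

    ok_rd = fits[fits.rd_applicable]
    ok_pw = fits[fits.pow_applicable]
    print(f"strength-porosity fits applicable: {len(ok_rd)}/{len(fits)}; "
          f"TS0 in [{ok_rd.TS0.min():.4g}, {ok_rd.TS0.max():.4g}] MPa, "
          f"kb in [{ok_rd.kb.min():.4g}, {ok_rd.kb.max():.4g}]")
    print(f"strength-pressure fits applicable: {len(ok_pw)}/{len(fits)}; "
          f"d in [{ok_pw.d.min():.3g}, {ok_pw.d.max():.3g}], "
          f"g in [{ok_pw.g.min():.4g}, {ok_pw.g.max():.4g}]")
    rej = fits[~(fits.rd_applicable & fits.pow_applicable)]
    print("rejected materials:", dict(zip(rej.material_id, rej.rd_reject_reason)))


if __name__ == "__main__":
    main()
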