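#!/usr/bin/env python
"""Refined PLS model and the multi-objective design space.

Refits the PLS model on the VIP > 1 variable subset and maps the ribbon
quality targets (TS >= 1 MPa; 0.6 <= SF <= 0.8) into its first-two-LV
score plane, intersected with the 95% confidence circle of score
distances. Writes the region mask, the analytical boundary polygon, the
per-observation membership table and a chart.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from rollcompact import design_space as ds
from rollcompact import pls, viz


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    desc = pd.read_csv(args.out / "descriptors.csv").drop(columns=["type"])
    profiles = pd.read_csv(args.out / "profiles.csv")
    fits = pd.read_csv(args.out / "compaction_fits.csv")
    X, Y, meta = pls.assemble_lvm_dataset(desc, profiles, fits)
    model = pls.PLSModelState.load(args.out / "pls_model.json")

    refined, kept = ds.refine_model(model, X, Y, seed=args.seed)
    refined.save(args.out / "pls_model_refined.json")
    print(f"refined model keeps {len(kept)} variables: {kept}")
    print(f"  {refined.n_components} LVs: R2Xcum={refined.r2x_cum:.1%}, "
          f"R2Ycum={refined.r2y_cum:.1%}, Q2Ycum={refined.q2y_cum:.1%}")

    dsmap = ds.map_targets(refined)
    np.savetxt(args.out / "design_space_mask.csv", dsmap.region.astype(int),
               fmt="%d", delimiter=",")
    with open(args.out / "design_space_region.json", "w") as fh:
        json.dump({"radius": dsmap.radius, "area_fraction": dsmap.area_fraction,
                   "boundary": dsmap.boundary}, fh, indent=1)

    membership = ds.project_material(refined, X, dsmap)
    membership = pd.concat([meta.reset_index(drop=True),
                            membership.reset_index(drop=True)], axis=1)
    membership.to_csv(args.out / "design_space_membership.csv", index=False,
                      float_format="%.6g")
    viz.plot_design_space(dsmap, membership, args.out / "design_space.png")

    truth = pd.read_csv(args.out / "ground_truth.csv")
    mem = membership.merge(truth[["material_id", "category"]], on="material_id")
    by_mat = mem.groupby(["category", "material_id"]).in_design_space.any()
    print(f"confidence radius {dsmap.radius:.2f}; design space covers "
          f"{dsmap.area_fraction:.1%} of the limit circle")
    for cat, grp in by_mat.groupby(level=0):
        print(f"  {cat}: {grp.mean():.0%} of materials reach the design space")


if __name__ == "__main__":
    main()
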