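#!/usr/bin/env python
"""PLS2 model of ribbon quality from descriptors, compaction coefficients
and pressure.

Assembles the modeling matrices (one observation per material x pressure,
materials with inapplicable fits excluded), picks the number of latent
variables from the cross-validated Q2 curve, fits the NIPALS PLS2 model,
and reports diagnostics, VIP ranking and regression coefficients.
"""

import argparse
from pathlib import Path

import pandas as pd

from rollcompact import pls


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--folds", type=int, default=7)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    desc = pd.read_csv(args.out / "descriptors.csv").drop(columns=["type"])
    profiles = pd.read_csv(args.out / "profiles.csv")
    fits = pd.read_csv(args.out / "compaction_fits.csv")
    X, Y, meta = pls.assemble_lvm_dataset(desc, profiles, fits)
    print(f"modeling dataset: {X.shape[0]} observations "
          f"({meta.material_id.nunique()} materials x "
          f"{meta.pressure_bar.nunique()} pressures), {X.shape[1]} predictors")

    a_max = min(10, X.shape[1])
    q2, _ = pls.cross_validate(X, Y, a_max, n_folds=args.folds, seed=args.seed)
    a = pls.select_components(q2)
    model = pls.fit_pls(X, Y, a)
    model.q2y_cum = float(q2[a - 1])
    _, model.rmsecv = pls.cross_validate(X, Y, a, n_folds=args.folds, seed=args.seed)
    model.save(args.out / "pls_model.json")

    vip_tab = pd.DataFrame({"variable": model.x_columns, "VIP": pls.vip(model)}
                           ).sort_values("VIP", ascending=False)
    vip_tab.to_csv(args.out / "vip.csv", index=False, float_format="%.6g")
    pls.coefficients(model).to_csv(args.out / "coefficients.csv", index=False,
                                   float_format="%.6g")

    print(f"selected {a} LVs: R2Xcum={model.r2x_cum:.1%}, "
          f"R2Ycum={model.r2y_cum:.1%}, Q2Ycum={model.q2y_cum:.1%}")
    print(f"RMSECV: TS {model.rmsecv[0]:.3g} MPa, SF {model.rmsecv[1]:.3g}")
    print("VIP ranking (VIP > 1 marks influential variables):")
    print(vip_tab[vip_tab.VIP > 1].to_string(index=False))
    semi, radius = pls.score_limits(model)
    outl = pls.hotelling_outliers(model)
    print(f"score-plot limits: Hotelling semi-axes {semi.round(2)}, "
          f"Euclidean r95 {radius:.2f}; {int(outl.sum())} observations outside "
          "the Hotelling ellipse")


if __name__ == "__main__":
    main()
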