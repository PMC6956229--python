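"""Static chart exports: TS-SF classification map and design-space plot."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_ts_sf_map", "plot_design_space"]


def plot_ts_sf_map(ts_sf_table, path, *, sf_band=(0.6, 0.8), ts_min=1.0):
    """TS vs SF scatter with the target region shaded."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    top = max(ts_sf_table["TS"].max() * 1.1, ts_min * 2)
    ax.axhspan(ts_min, top, xmin=0, xmax=1, color="none")
    ax.add_patch(plt.Rectangle((sf_band[0], ts_min), sf_band[1] - sf_band[0],
                               top - ts_min, color="red", alpha=0.15, zorder=0))
    for mid, grp in ts_sf_table.groupby("material_id"):
        grp = grp.sort_values("pressure_bar")
        ax.plot(grp["SF"], grp["TS"], "-o", ms=3, lw=0.6, alpha=0.6)
    ax.set_xlabel("solid fraction")
    ax.set_ylabel("tensile strength (MPa)")
    ax.set_yscale("log")
    ax.set_title("ribbon quality map with target region")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_design_space(dsmap, membership, path):
    """Score-space design space: constraint masks, limit circle, projections."""
    fig, ax = plt.subplots(figsize=(6, 5.5))
    extent = (dsmap.t1[0], dsmap.t1[-1], dsmap.t2[0], dsmap.t2[-1])
    ax.imshow(np.where(dsmap.ts_ok, 1.0, np.nan), origin="lower", extent=extent,
              cmap="YlOrBr", alpha=0.25, vmin=0, vmax=2, aspect="auto")
    ax.imshow(np.where(dsmap.sf_ok, 1.0, np.nan), origin="lower", extent=extent,
              cmap="Blues", alpha=0.25, vmin=0, vmax=2, aspect="auto")
    ax.imshow(np.where(dsmap.region, 1.0, np.nan), origin="lower", extent=extent,
              cmap="Reds", alpha=0.5, vmin=0, vmax=2, aspect="auto")
    theta = np.linspace(0, 2 * np.pi, 400)
    ax.plot(dsmap.radius * np.cos(theta), dsmap.radius * np.sin(theta), "k--", lw=1)
    if membership is not None:
        inside = membership["in_design_space"]
        ax.scatter(membership["t1"][~inside], membership["t2"][~inside],
                   s=8, c="gray", alpha=0.5, label="outside")
        ax.scatter(membership["t1"][inside], membership["t2"][inside],
                   s=10, c="crimson", label="inside")
        ax.legend(loc="upper right", fontsize=8)
    ax.set_xlabel("t1")
    ax.set_ylabel("t2")
    ax.set_title("multi-objective design space (first two LVs)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
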