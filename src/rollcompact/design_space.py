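"""Multi-objective design space in latent-variable score space.

After the full PLS model identifies the influential variables (VIP > 1),
a refined model is refit on that subset and the ribbon quality targets
(TS >= 1 MPa; 0.6 <= SF <= 0.8) are mapped into its first-two-LV score
plane. Because the 2-LV prediction of each response is affine in the
scores (y_hat = y_mean + t1*c1 + t2*c2, back-scaled), each target is a
half-plane (TS) or a band (SF); the design space is their intersection
with the 95% confidence circle of observed score distances. Both a
rasterized grid mask and the analytical polygon of the region are
produced; each projected material also carries its full-A prediction so
the 2-LV approximation can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from . import pls
from .pls import PLSModelState, fit_pls, vip, score_limits, PLSError

__all__ = ["DesignSpaceMap", "refine_model", "map_targets", "project_material"]


@dataclass
class DesignSpaceMap:
    t1: np.ndarray                 # grid axis, LV1
    t2: np.ndarray                 # grid axis, LV2
    ts_ok: np.ndarray              # grid masks (len(t2) x len(t1))
    sf_ok: np.ndarray
    inside_limit: np.ndarray
    region: np.ndarray
    radius: float                  # confidence-circle radius
    area_fraction: float           # region area / circle area
    boundary: list[tuple[float, float]]   # analytical region polygon vertices
    predicted_ts: np.ndarray
    predicted_sf: np.ndarray


def refine_model(model: PLSModelState, X, Y, n_components: int | None = None,
                 vip_cutoff: float = 1.0, **cv_kw) -> tuple[PLSModelState, list[str]]:
    """Refit the PLS model on the VIP > cutoff column subset.

    ``X`` must be a DataFrame carrying the full model's columns. The
    number of components defaults to min(full model A, new column count);
    pass ``n_components`` to override. Returns ``(refined_model, kept_columns)``.
    """
    v = vip(model)
    kept = [c for c, vj in zip(model.x_columns, v) if vj > vip_cutoff]
    if len(kept) < 2:
        raise PLSError(f"VIP > {vip_cutoff} keeps {len(kept)} variable(s); need >= 2")
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float), columns=model.x_columns)
    a = n_components or min(model.n_components, len(kept))
    refined = fit_pls(X[kept], Y, a, y_columns=model.y_columns)
    q2_curve, rmsecv = pls.cross_validate(X[kept], Y, a, y_columns=model.y_columns,
                                          **cv_kw)
    refined.q2y_curve = q2_curve
    refined.q2y_cum = float(q2_curve[-1])
    refined.rmsecv = rmsecv
    return refined, kept


def _grid_predictions(model: PLSModelState, t1: np.ndarray, t2: np.ndarray):
    """2-LV predictions of every response over the (t1, t2) grid."""
    C2 = model.C[:, :2]                       # q x 2
    if np.any(np.linalg.norm(C2, axis=1) == 0):
        raise PLSError("degenerate Y-loadings: a response has zero loading on both LVs")
    G1, G2 = np.meshgrid(t1, t2)
    ys = np.stack([G1, G2], axis=-1) @ C2.T   # scaled-unit predictions
    y = ys * model.y_scaling.std + model.y_scaling.mean
    return G1, G2, y


def map_targets(model: PLSModelState, *, ts_min: float = 1.0,
                sf_band: tuple[float, float] = (0.6, 0.8), level: float = 0.95,
                n_grid: int = 201, radius: float | None = None,
                limit: str = "euclidean") -> DesignSpaceMap:
    """Map the ribbon quality targets into the first-two-LV score plane.

    The confidence limit is the empirical ``level`` percentile of the
    training scores' Euclidean distances (``limit='euclidean'``, the
    default) or the circumscribed Hotelling radius (``limit='hotelling'``).
    The grid spans 1.2x the limit radius at ``n_grid`` points per axis.
    """
    ts_idx = model.y_columns.index("TS") if "TS" in model.y_columns else 0
    sf_idx = model.y_columns.index("SF") if "SF" in model.y_columns else 1

    semi, r_euclid = score_limits(model, level)
    if radius is None:
        radius = r_euclid if limit == "euclidean" else float(np.max(semi))
    span = 1.2 * radius
    t1 = np.linspace(-span, span, n_grid)
    t2 = np.linspace(-span, span, n_grid)
    G1, G2, y = _grid_predictions(model, t1, t2)

    ts_ok = y[..., ts_idx] >= ts_min
    sf_ok = (y[..., sf_idx] >= sf_band[0]) & (y[..., sf_idx] <= sf_band[1])
    inside = G1**2 + G2**2 <= radius**2
    region = ts_ok & sf_ok & inside

    cell = (t1[1] - t1[0]) * (t2[1] - t2[0])
    circle_area = np.pi * radius**2
    area_fraction = float(region.sum() * cell / circle_area)

    boundary = _region_polygon(model, ts_idx, sf_idx, ts_min, sf_band, radius)

    return DesignSpaceMap(t1=t1, t2=t2, ts_ok=ts_ok, sf_ok=sf_ok,
                          inside_limit=inside, region=region, radius=radius,
                          area_fraction=area_fraction, boundary=boundary,
                          predicted_ts=y[..., ts_idx], predicted_sf=y[..., sf_idx])


def _halfplane(normal: np.ndarray, offset: float, extent: float) -> Polygon:
    """Polygon covering {t : normal . t >= offset} within a bounding box."""
    nx, ny = normal / np.linalg.norm(normal)
    c = offset / np.linalg.norm(normal)
    # big square rotated so one edge is the boundary line
    u = np.array([nx, ny])
    v = np.array([-ny, nx])
    p0 = c * u
    big = 4 * extent
    pts = [p0 - big * v, p0 + big * v, p0 + big * v + big * u, p0 - big * v + big * u]
    return Polygon(pts)


def _region_polygon(model, ts_idx, sf_idx, ts_min, sf_band, radius,
                    circle_resolution: int = 720) -> list[tuple[float, float]]:
    """Analytical (half-plane ∩ band ∩ circle) region boundary vertices.

    In scaled units the 2-LV prediction of response k is t . c_k, so each
    constraint is linear in (t1, t2); the circle is approximated by a
    high-resolution polygon for the intersection.
    """
    C2 = model.C[:, :2]
    ystd, ymean = model.y_scaling.std, model.y_scaling.mean
    shape = Point(0.0, 0.0).buffer(radius, quad_segs=circle_resolution // 4)
    # TS >= ts_min  <=>  c_ts . t >= (ts_min - mean)/std
    shape = shape.intersection(
        _halfplane(C2[ts_idx], (ts_min - ymean[ts_idx]) / ystd[ts_idx], radius))
    lo = (sf_band[0] - ymean[sf_idx]) / ystd[sf_idx]
    hi = (sf_band[1] - ymean[sf_idx]) / ystd[sf_idx]
    shape = shape.intersection(_halfplane(C2[sf_idx], lo, radius))
    shape = shape.intersection(_halfplane(-C2[sf_idx], -hi, radius))
    if shape.is_empty:
        return []
    if shape.geom_type == "MultiPolygon":
        shape = max(shape.geoms, key=lambda g: g.area)
    return [(float(x), float(y)) for x, y in zip(*shape.exterior.xy)]


def project_material(model: PLSModelState, x_new: pd.DataFrame, dsmap: DesignSpaceMap,
                     *, ts_min: float = 1.0,
                     sf_band: tuple[float, float] = (0.6, 0.8)) -> pd.DataFrame:
    """Project new observations into score space and flag design-space membership.

    ``x_new`` may carry extra columns (e.g. the VIP-discarded ones); the
    refined model's columns are selected by name and any missing column
    raises naming it. Membership uses the exact 2-LV constraint algebra
    plus the confidence circle; the full-A prediction is reported
    alongside for audit.
    """
    missing = [c for c in model.x_columns if c not in x_new.columns]
    if missing:
        raise PLSError(f"x_new missing required column(s): {missing}")
    Xm = x_new[model.x_columns]
    t = model.scores(Xm)
    y2 = model.predict_from_scores(t[:, :2], 2)
    yfull = model.predict(Xm)
    ts_idx = model.y_columns.index("TS") if "TS" in model.y_columns else 0
    sf_idx = model.y_columns.index("SF") if "SF" in model.y_columns else 1
    dist = np.linalg.norm(t[:, :2], axis=1)
    inside = ((y2[:, ts_idx] >= ts_min)
              & (y2[:, sf_idx] >= sf_band[0]) & (y2[:, sf_idx] <= sf_band[1])
              & (dist <= dsmap.radius))
    out = pd.DataFrame({
        "t1": t[:, 0], "t2": t[:, 1],
        "pred_TS_2lv": y2[:, ts_idx], "pred_SF_2lv": y2[:, sf_idx],
        "pred_TS_full": yfull[:, ts_idx], "pred_SF_full": yfull[:, sf_idx],
        "score_distance": dist, "in_design_space": inside,
    })
    out.index = x_new.index
    return out
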