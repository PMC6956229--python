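"""Empirical compaction models.

Two-parameter strength laws fitted per material across the hydraulic
pressure grid:

* Ryshkewitch-Duckworth (R-D), an exponential strength-porosity law
  TS = TS0 * exp(-kb * eps). TS0 is the extrapolated strength of the
  fully dense compact; kb quantifies how fast strength decays with
  porosity (a larger kb means weaker inter-particle bonding). Fitted as
  a straight line ln(TS) = ln(TS0) - kb*eps by ordinary least squares,
  with R^2 reported in log space — the linearized form in which the
  relation is conventionally plotted.

* Power strength-pressure law TS = d * P^g. d sets the strength scale
  at unit pressure (initial ribbonability); g is the pressure
  sensitivity (g > 1 concave-up profiles, g < 1 saturating ones).
  Fitted by Levenberg-Marquardt in raw space, started from a log-log
  OLS estimate, with R^2 reported in raw space.

A fit is screened for applicability: at least 3 valid points, R^2 >= 0.7
and a physically plausible strength scale (TS0 below a configurable cap,
defaulting to 1000 MPa — fits on near-constant porosity ranges can
extrapolate to absurd zero-porosity strengths). Non-monotone TS
sequences are flagged as metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "RDFit", "PowerFit", "fit_rd", "predict_rd", "fit_power", "predict_power",
    "R2_THRESHOLD", "TS0_CAP_MPA",
]

R2_THRESHOLD = 0.7
TS0_CAP_MPA = 1000.0

REJECT_REASONS = ("none", "low_r2", "non_monotone", "unreasonable_coeff", "too_few_points")


@dataclass(frozen=True)
class RDFit:
    ts0: float        # MPa, zero-porosity tensile strength
    kb: float         # bonding-capacity slope
    r2: float         # in ln(TS) space
    n_points: int
    applicable: bool = False
    reject_reason: str = "none"
    non_monotone: bool = False   # metadata flag, not itself a rejection


@dataclass(frozen=True)
class PowerFit:
    d: float          # MPa * bar^-g
    g: float          # pressure sensitivity exponent
    r2: float         # in raw TS space
    n_points: int
    applicable: bool = False
    reject_reason: str = "none"
    non_monotone: bool = False


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 0.0
    return 1.0 - ss_res / ss_tot


def _valid_mask(x: np.ndarray, y: np.ndarray, x_positive: bool) -> np.ndarray:
    ok = np.isfinite(x) & np.isfinite(y) & (y > 0)
    if x_positive:
        ok &= x > 0
    return ok


def _screen(fit, x_sorted_ts: np.ndarray, ts0_cap: float, r2_threshold: float):
    """Shared applicability screening; returns an updated (frozen) fit."""
    non_mono = bool(np.any(np.diff(x_sorted_ts) < 0))
    scale = fit.ts0 if isinstance(fit, RDFit) else fit.d
    if fit.n_points < 3:
        reason = "too_few_points"
    elif not np.isfinite(fit.r2) or fit.r2 < r2_threshold:
        reason = "low_r2"
    elif not np.isfinite(scale) or scale <= 0 or (isinstance(fit, RDFit) and fit.ts0 > ts0_cap):
        reason = "unreasonable_coeff"
    else:
        reason = "none"
    return replace(fit, applicable=(reason == "none"), reject_reason=reason,
                   non_monotone=non_mono)


def fit_rd(eps, ts, *, r2_threshold: float = R2_THRESHOLD,
           ts0_cap: float = TS0_CAP_MPA) -> RDFit:
    """Fit TS = TS0*exp(-kb*eps) by OLS of ln(TS) on porosity.

    Points with missing or non-positive TS are excluded, never imputed.
    The fit is permutation-invariant in point order.
    """
    eps = np.asarray(eps, dtype=float)
    ts = np.asarray(ts, dtype=float)
    ok = _valid_mask(eps, ts, x_positive=False)
    eps, ts = eps[ok], ts[ok]
    n = eps.size
    if n < 3:
        return RDFit(np.nan, np.nan, np.nan, n, False, "too_few_points")
    slope, intercept = np.polyfit(eps, np.log(ts), 1)
    fit = RDFit(ts0=float(np.exp(intercept)), kb=float(-slope),
                r2=_r2(np.log(ts), slope * eps + intercept), n_points=n)
    order = np.argsort(-eps)  # TS should increase as porosity drops
    return _screen(fit, ts[order], ts0_cap, r2_threshold)


def predict_rd(fit: RDFit, eps) -> np.ndarray | float:
    """TS = TS0*exp(-kb*eps); strictly decreasing in porosity for kb > 0."""
    return fit.ts0 * np.exp(-fit.kb * np.asarray(eps, dtype=float))


def fit_power(pressure, ts, *, r2_threshold: float = R2_THRESHOLD,
              max_iter: int = 200) -> PowerFit:
    """Fit TS = d*P^g by Levenberg-Marquardt in raw space.

    The optimizer is started from the log-log OLS estimate. If LM fails
    to converge, the log-log coefficients are reported with the fit
    rejected (low_r2).
    """
    p = np.asarray(pressure, dtype=float)
    ts = np.asarray(ts, dtype=float)
    ok = _valid_mask(p, ts, x_positive=True)
    p, ts = p[ok], ts[ok]
    n = p.size
    if n < 3:
        return PowerFit(np.nan, np.nan, np.nan, n, False, "too_few_points")

    g0, logd0 = np.polyfit(np.log(p), np.log(ts), 1)
    d0 = float(np.exp(logd0))
    try:
        import warnings

        from scipy.optimize import OptimizeWarning

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)  # covariance unused
            (d, g), _ = curve_fit(lambda x, d, g: d * x**g, p, ts, p0=[d0, g0],
                                  maxfev=max_iter * (n + 2), method="lm")
        converged = np.isfinite(d) and np.isfinite(g)
    except RuntimeError:
        converged = False
    if not converged:
        fit = PowerFit(d0, float(g0), -np.inf, n, False, "low_r2")
        order = np.argsort(p)
        return replace(fit, non_monotone=bool(np.any(np.diff(ts[order]) < 0)))
    fit = PowerFit(d=float(d), g=float(g), r2=_r2(ts, d * p**g), n_points=n)
    order = np.argsort(p)
    return _screen(fit, ts[order], np.inf, r2_threshold)


def predict_power(fit: PowerFit, pressure) -> np.ndarray | float:
    """TS = d*P^g; strictly increasing in P for d, g > 0."""
    return fit.d * np.asarray(pressure, dtype=float) ** fit.g


def fit_profile(profile) -> tuple[RDFit, PowerFit]:
    """Both compaction fits for one CompactionProfile."""
    return (fit_rd(profile.porosity, profile.tensile_strength),
            fit_power(profile.pressures, profile.tensile_strength))


def fit_table(profiles: dict) -> "pd.DataFrame":
    """Per-material coefficient table for a dict of profiles."""
    import pandas as pd

    rows = []
    for mid, prof in profiles.items():
        if prof.non_compactable:
            rd = RDFit(np.nan, np.nan, np.nan, 0, False, "too_few_points")
            pw = PowerFit(np.nan, np.nan, np.nan, 0, False, "too_few_points")
        else:
            rd, pw = fit_profile(prof)
        rows.append({
            "material_id": mid,
            "TS0": rd.ts0, "kb": rd.kb, "r2_rd": rd.r2,
            "rd_applicable": rd.applicable, "rd_reject_reason": rd.reject_reason,
            "d": pw.d, "g": pw.g, "r2_pow": pw.r2,
            "pow_applicable": pw.applicable, "pow_reject_reason": pw.reject_reason,
        })
    return pd.DataFrame(rows)
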