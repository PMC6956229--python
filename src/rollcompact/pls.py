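"""Multi-response partial least squares (PLS2) by NIPALS.

The X-block combines the 22 powder descriptors, the four compaction
descriptors (TS0, kb, d, g) and the hydraulic pressure; the Y-block is
the pair of ribbon quality attributes (TS, SF). One observation is one
material at one pressure level.

Conventions follow common chemometrics practice: columns are autoscaled
(mean-centered, unit variance), components are extracted by NIPALS with
X-deflation, weight vectors are unit length with the sign fixed so the
first nonzero element is positive, and diagnostics are the cumulative
explained variances R2X/R2Y plus the cross-validated Q2Y from a
venetian-blind fold assignment over a seed-shuffled row order.

Variable importance in projection:

    VIP_j = sqrt( p * sum_a SSY_a * w_ja^2 / sum_a SSY_a )

with SSY_a the Y-variance explained by component a and w_a the unit
weight vectors, so that the mean of squared VIPs is exactly 1 and
VIP > 1 marks above-average influence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PLSModelState", "autoscale", "fit_pls", "cross_validate", "vip",
    "coefficients", "score_limits", "select_components", "assemble_lvm_dataset",
]

NIPALS_TOL = 1e-10
# power iteration converges linearly at the ratio of the two leading
# eigenvalues of X'YY'X; near-degenerate directions (common with two
# correlated responses) need thousands of iterations at tol 1e-10
NIPALS_MAX_ITER = 20_000


class PLSError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# preprocessing

@dataclass
class ScalingStats:
    mean: np.ndarray
    std: np.ndarray   # ddof=1

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.std

    def inverse(self, Xs: np.ndarray) -> np.ndarray:
        return np.asarray(Xs, dtype=float) * self.std + self.mean


def autoscale(X: np.ndarray, columns=None) -> tuple[np.ndarray, ScalingStats]:
    """Mean-center and scale each column to unit variance (ddof=1).

    Raises naming the offending column if any column has zero variance.
    """
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=1)
    bad = np.where(std == 0)[0]
    if bad.size:
        names = [columns[i] if columns is not None else f"col{i}" for i in bad]
        raise PLSError(f"zero-variance column(s): {names}")
    return (X - mean) / std, ScalingStats(mean, std)


# ---------------------------------------------------------------------------
# model state

@dataclass
class PLSModelState:
    """Fitted PLS2 model: preprocessing stats, latent structure, diagnostics."""

    x_columns: list[str]
    y_columns: list[str]
    x_scaling: ScalingStats
    y_scaling: ScalingStats
    W: np.ndarray          # p x A unit X-weights
    P: np.ndarray          # p x A X-loadings
    C: np.ndarray          # q x A Y-loadings
    T: np.ndarray          # n x A training scores
    n_components: int
    r2x_per_component: np.ndarray
    r2x_cum: float
    r2y_per_component: np.ndarray
    r2y_cum: float
    ssy_per_component: np.ndarray   # explained Y sum of squares (scaled units)
    q2y_cum: float | None = None
    q2y_curve: np.ndarray | None = None
    rmsec: np.ndarray | None = None    # per response, raw units
    rmsecv: np.ndarray | None = None

    @property
    def rotation(self) -> np.ndarray:
        """R = W (P'W)^-1, so scores of new data are X_scaled @ R."""
        return self.W @ np.linalg.inv(self.P.T @ self.W)

    @property
    def b_scaled(self) -> np.ndarray:
        """Regression coefficients in scaled units: Y_s ~ X_s @ B."""
        return self.rotation @ self.C.T

    def scores(self, X) -> np.ndarray:
        """Project (raw-unit) observations onto the latent space."""
        return self.x_scaling.transform(X) @ self.rotation

    def predict(self, X, n_components: int | None = None) -> np.ndarray:
        """Predict Y in raw units; optionally truncate to the first LVs."""
        a = self.n_components if n_components is None else n_components
        t = self.scores(X)[:, :a]
        return self.y_scaling.inverse(t @ self.C[:, :a].T)

    def predict_from_scores(self, t: np.ndarray, n_components: int = 2) -> np.ndarray:
        """Predict Y (raw units) directly from score-space coordinates."""
        t = np.atleast_2d(np.asarray(t, dtype=float))
        return self.y_scaling.inverse(t @ self.C[:, :n_components].T)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()
        return {
            "x_columns": self.x_columns, "y_columns": self.y_columns,
            "x_mean": arr(self.x_scaling.mean), "x_std": arr(self.x_scaling.std),
            "y_mean": arr(self.y_scaling.mean), "y_std": arr(self.y_scaling.std),
            "W": arr(self.W), "P": arr(self.P), "C": arr(self.C), "T": arr(self.T),
            "n_components": self.n_components,
            "r2x_per_component": arr(self.r2x_per_component), "r2x_cum": self.r2x_cum,
            "r2y_per_component": arr(self.r2y_per_component), "r2y_cum": self.r2y_cum,
            "ssy_per_component": arr(self.ssy_per_component),
            "q2y_cum": self.q2y_cum, "q2y_curve": arr(self.q2y_curve),
            "rmsec": arr(self.rmsec), "rmsecv": arr(self.rmsecv),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModelState":
        def arr(a):
            return None if a is None else np.asarray(a, dtype=float)
        return cls(
            x_columns=list(d["x_columns"]), y_columns=list(d["y_columns"]),
            x_scaling=ScalingStats(arr(d["x_mean"]), arr(d["x_std"])),
            y_scaling=ScalingStats(arr(d["y_mean"]), arr(d["y_std"])),
            W=arr(d["W"]), P=arr(d["P"]), C=arr(d["C"]), T=arr(d["T"]),
            n_components=int(d["n_components"]),
            r2x_per_component=arr(d["r2x_per_component"]), r2x_cum=d["r2x_cum"],
            r2y_per_component=arr(d["r2y_per_component"]), r2y_cum=d["r2y_cum"],
            ssy_per_component=arr(d["ssy_per_component"]),
            q2y_cum=d.get("q2y_cum"), q2y_curve=arr(d.get("q2y_curve")),
            rmsec=arr(d.get("rmsec")), rmsecv=arr(d.get("rmsecv")),
        )

    @classmethod
    def load(cls, path) -> "PLSModelState":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# fitting

def _fix_sign(w: np.ndarray) -> float:
    nz = np.nonzero(w)[0]
    if nz.size and w[nz[0]] < 0:
        return -1.0
    return 1.0


def _nipals_component(Xk: np.ndarray, Yk: np.ndarray, index: int):
    """One NIPALS PLS2 component on (already deflated) scaled blocks."""
    u = Yk[:, int(np.argmax(Yk.var(axis=0)))].copy()
    if not np.any(u):
        u = Yk[:, 0] + 1e-12
    t_old = np.zeros(Xk.shape[0])
    for _ in range(NIPALS_MAX_ITER):
        w = Xk.T @ u
        nw = np.linalg.norm(w)
        if nw == 0:
            raise PLSError(f"NIPALS breakdown at component {index + 1}: zero weight vector")
        w /= nw
        t = Xk @ w
        c = Yk.T @ t / (t @ t)
        u = Yk @ c / (c @ c)
        if np.linalg.norm(t - t_old) <= NIPALS_TOL * max(np.linalg.norm(t), 1e-300):
            break
        t_old = t
    else:
        raise PLSError(f"NIPALS did not converge for component {index + 1}")
    s = _fix_sign(w)
    w, t, c = s * w, s * t, s * c
    p = Xk.T @ t / (t @ t)
    return w, t, p, c


def fit_pls(X, Y, n_components: int, *, x_columns=None, y_columns=None) -> PLSModelState:
    """Fit a PLS2 model with ``n_components`` latent variables by NIPALS.

    X and Y are raw-unit matrices (or DataFrames); autoscaling is applied
    internally and stored in the model state.
    """
    if isinstance(X, pd.DataFrame):
        x_columns = list(X.columns)
        X = X.to_numpy(dtype=float)
    if isinstance(Y, pd.DataFrame):
        y_columns = list(Y.columns)
        Y = Y.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    n, p = X.shape
    q = Y.shape[1]
    x_columns = x_columns or [f"x{j}" for j in range(p)]
    y_columns = y_columns or [f"y{j}" for j in range(q)]
    if not np.isfinite(X).all() or not np.isfinite(Y).all():
        raise PLSError("modeling matrices contain missing/non-finite cells")
    if n_components > min(n - 1, p):
        raise PLSError(f"n_components={n_components} exceeds rank bound {min(n - 1, p)}")

    Xs, xstats = autoscale(X, x_columns)
    Ys, ystats = autoscale(Y, y_columns)
    ssx_tot = float(np.sum(Xs**2))
    ssy_tot = float(np.sum(Ys**2))

    Xk, Yk = Xs.copy(), Ys.copy()
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    C = np.zeros((q, n_components))
    T = np.zeros((n, n_components))
    r2x = np.zeros(n_components)
    ssy_a = np.zeros(n_components)
    for a in range(n_components):
        w, t, pl, c = _nipals_component(Xk, Yk, a)
        W[:, a], T[:, a], P[:, a], C[:, a] = w, t, pl, c
        tt = float(t @ t)
        r2x[a] = tt * float(pl @ pl) / ssx_tot
        ssy_a[a] = tt * float(c @ c)
        Xk = Xk - np.outer(t, pl)
        Yk = Yk - np.outer(t, c)

    resid = Ys - T @ C.T
    r2y_cum = 1.0 - float(np.sum(resid**2)) / ssy_tot
    r2y_per = ssy_a / ssy_tot

    model = PLSModelState(
        x_columns=x_columns, y_columns=y_columns,
        x_scaling=xstats, y_scaling=ystats,
        W=W, P=P, C=C, T=T, n_components=n_components,
        r2x_per_component=r2x, r2x_cum=float(r2x.sum()),
        r2y_per_component=r2y_per, r2y_cum=r2y_cum,
        ssy_per_component=ssy_a,
    )
    # structural invariants asserted on every fit
    G = T.T @ T
    off = np.abs(G - np.diag(np.diag(G))).max(initial=0.0)
    if off > 1e-8 * max(np.diag(G).max(), 1e-300):
        raise PLSError("score orthogonality violated")
    v = vip(model)
    if abs(np.mean(v**2) - 1.0) > 1e-8:
        raise PLSError("VIP normalization violated")
    model.rmsec = np.sqrt(np.mean((Y - model.predict(X)) ** 2, axis=0))
    return model


def vip(model: PLSModelState) -> np.ndarray:
    """Variable importance in projection for every X column (mean VIP^2 = 1)."""
    ssy = model.ssy_per_component
    W2 = model.W**2
    p = model.W.shape[0]
    return np.sqrt(p * (W2 @ ssy) / ssy.sum())


def coefficients(model: PLSModelState) -> pd.DataFrame:
    """Regression coefficients per (X column, response), scaled and raw units.

    Raw-unit coefficients express dY/dX in original measurement units;
    scaled coefficients are directly comparable across variables.
    """
    B = model.b_scaled
    rows = []
    for j, xc in enumerate(model.x_columns):
        for k, yc in enumerate(model.y_columns):
            raw = B[j, k] * model.y_scaling.std[k] / model.x_scaling.std[j]
            rows.append({"x": xc, "y": yc, "coef_scaled": B[j, k], "coef_raw": raw})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cross validation & component selection

def _venetian_folds(n: int, n_folds: int, seed: int) -> np.ndarray:
    """Fold assignment: rows are shuffled once (seeded), then dealt round-robin."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    folds[order] = np.arange(n) % n_folds
    return folds


def cross_validate(X, Y, a_max: int, *, n_folds: int = 7, seed: int = 0,
                   x_columns=None, y_columns=None):
    """Q2Ycum and RMSECV over 1..a_max components by venetian-blind CV.

    Returns ``(q2_curve, rmsecv)`` where ``q2_curve[a-1]`` is the
    cumulative Q2 for an a-component model (1 - PRESS/SS on centered Y)
    and ``rmsecv`` the per-response RMSECV at ``a_max`` components.
    """
    if isinstance(X, pd.DataFrame):
        x_columns = list(X.columns)
        X = X.to_numpy(dtype=float)
    if isinstance(Y, pd.DataFrame):
        y_columns = list(Y.columns)
        Y = Y.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    n = X.shape[0]
    if n < 2 * n_folds:
        raise PLSError(f"need at least {2 * n_folds} rows for {n_folds}-fold CV")

    folds = _venetian_folds(n, n_folds, seed)
    # PRESS accumulated on globally scaled Y so responses weigh equally
    _, ystats = autoscale(Y, y_columns)
    press = np.zeros((a_max, Y.shape[1]))
    for f in range(n_folds):
        test = folds == f
        train = ~test
        if Y[train].std(axis=0).min() == 0:
            import warnings
            warnings.warn(f"fold {f}: a response has no variation in training rows")
        model = fit_pls(X[train], Y[train], a_max,
                        x_columns=x_columns, y_columns=y_columns)
        for a in range(1, a_max + 1):
            pred = model.predict(X[test], n_components=a)
            press[a - 1] += np.sum(((Y[test] - pred) / ystats.std) ** 2, axis=0)

    ss = np.sum(ystats.transform(Y) ** 2, axis=0)
    q2_curve = 1.0 - press.sum(axis=1) / ss.sum()
    rmsecv = np.sqrt(press[a_max - 1] / n) * ystats.std
    return q2_curve, rmsecv


def select_components(q2_curve: np.ndarray, gain: float = 0.01, a_cap: int = 10) -> int:
    """Smallest A at which the Q2 gain of the next component drops below ``gain``."""
    a_max = min(len(q2_curve), a_cap)
    for a in range(1, a_max):
        if q2_curve[a] - q2_curve[a - 1] < gain:
            return a
    return a_max


def score_limits(model: PLSModelState, level: float = 0.95,
                 components: tuple[int, int] = (0, 1)):
    """Confidence limits for 2-LV score plots.

    Returns ``(ellipse_semiaxes, euclidean_radius)``: the Hotelling T^2
    ellipse semi-axes for the chosen two components (F-distribution
    based) and the empirical ``level`` percentile of the observations'
    Euclidean score distances from the origin.
    """
    t = model.T[:, list(components)]
    n = t.shape[0]
    if n < 3:
        raise PLSError("need at least 3 observations for score limits")
    t2_lim = 2.0 * (n - 1) / (n - 2) * stats.f.ppf(level, 2, n - 2)
    semi = np.sqrt(t2_lim * t.var(axis=0, ddof=1))
    dist = np.linalg.norm(t, axis=1)
    radius = float(np.percentile(dist, 100.0 * level))
    return semi, radius


def hotelling_outliers(model: PLSModelState, level: float = 0.95,
                       components: tuple[int, int] = (0, 1)) -> np.ndarray:
    """Boolean mask of training observations outside the Hotelling ellipse."""
    t = model.T[:, list(components)]
    n = t.shape[0]
    t2 = np.sum((t / t.std(axis=0, ddof=1)) ** 2, axis=1)
    lim = 2.0 * (n - 1) / (n - 2) * stats.f.ppf(level, 2, n - 2)
    return t2 > lim


# ---------------------------------------------------------------------------
# dataset assembly

def assemble_lvm_dataset(descriptors: pd.DataFrame, profile_table: pd.DataFrame,
                         fit_table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Join descriptor, profile and fit tables into PLS X/Y blocks.

    One row per material x pressure. Materials lacking applicable
    compaction fits (either model rejected) or any TS/SF value are
    excluded, mirroring the reduction of the library to the modellable
    subset. Returns ``(X, Y, meta)``.
    """
    fits = fit_table[fit_table["rd_applicable"] & fit_table["pow_applicable"]]
    fits = fits[["material_id", "TS0", "kb", "d", "g"]]
    desc = descriptors.merge(fits, on="material_id", how="inner")
    rows = profile_table.dropna(subset=["TS", "SF"]).merge(desc, on="material_id", how="inner")
    x_cols = [c for c in descriptors.columns if c != "material_id"] + ["kb", "TS0", "d", "g"]
    X = rows[x_cols].copy()
    X["P"] = rows["pressure_bar"].to_numpy(dtype=float)
    Y = rows[["TS", "SF"]].copy()
    meta = rows[["material_id", "pressure_bar"]].copy()
    return X, Y, meta
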