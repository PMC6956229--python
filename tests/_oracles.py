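"""Independent reference implementations used only as test oracles."""

import numpy as np


def svd_pls2(X, Y, n_components):
    """SVD-based PLS2 oracle (same X-deflation convention as NIPALS).

    Each weight vector is the leading left singular vector of the
    deflated cross-covariance X'Y; scores, loadings and deflation follow
    the standard two-block construction. Returns (W, P, C).
    """
    Xk = X.copy()
    Yk = Y.copy()
    p, q = X.shape[1], Y.shape[1]
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    C = np.zeros((q, n_components))
    for a in range(n_components):
        u_, s_, vt_ = np.linalg.svd(Xk.T @ Yk, full_matrices=False)
        w = u_[:, 0]
        nz = np.nonzero(w)[0]
        if w[nz[0]] < 0:
            w = -w
        t = Xk @ w
        pl = Xk.T @ t / (t @ t)
        c = Yk.T @ t / (t @ t)
        W[:, a], P[:, a], C[:, a] = w, pl, c
        Xk = Xk - np.outer(t, pl)
        Yk = Yk - np.outer(t, c)
    return W, P, C


def oracle_predict(X_new, xstats, ystats, W, P, C):
    Xs = xstats.transform(X_new)
    B = W @ np.linalg.inv(P.T @ W) @ C.T
    return ystats.inverse(Xs @ B)


def brute_force_label(points):
    """Independent RCBCS rule evaluator: explicit target-region logic.

    points: iterable of (pressure, SF, TS) tuples; TS may be NaN.
    """
    in_target = [(p, sf, ts) for p, sf, ts in points
                 if np.isfinite(ts) and 0.6 <= sf <= 0.8 and ts >= 1.0]
    dense_strong = [(p, sf, ts) for p, sf, ts in points
                    if np.isfinite(ts) and sf > 0.8 and ts >= 1.0]
    if in_target:
        sub = "A" if any(p in (30, 50, 70) for p, _, _ in in_target) else "B"
        return "I" + sub
    if dense_strong:
        sub = "A" if any(p in (30, 50, 70) for p, _, _ in dense_strong) else "B"
        return "II" + sub
    return "III"
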