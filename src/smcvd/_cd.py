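"""Numba kernels for cyclic coordinate descent under four penalties.

Penalty codes: 0 = lasso, 1 = elastic net, 2 = SCAD, 3 = MCP. Kernels assume
columns of ``X`` with mean-square one (standardised predictors) so each
univariate update is the exact minimiser of the coordinate objective, which
makes the full objective non-increasing sweep by sweep. ``alpha`` is the
elastic-net mixing weight; ``shape`` is SCAD's ``a`` or MCP's ``gamma``
(ignored by lasso / elastic net).
"""

import numpy as np
from numba import njit

LASSO, ENET, SCAD, MCP = 0, 1, 2, 3


@njit(cache=True)
def _soft(z, t):
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


@njit(cache=True)
def threshold_update(z, lam, kind, alpha, shape):
    """Exact minimiser of 0.5*(b - z)^2 + P(b; lam) for each penalty family."""
    if kind == LASSO:
        return _soft(z, lam)
    if kind == ENET:
        return _soft(z, lam * alpha) / (1.0 + lam * (1.0 - alpha))
    az = abs(z)
    if kind == SCAD:
        a = shape
        if az <= 2.0 * lam:
            return _soft(z, lam)
        if az <= a * lam:
            return _soft(z, a * lam / (a - 1.0)) / (1.0 - 1.0 / (a - 1.0))
        return z
    # MCP (firm thresholding)
    g = shape
    if az <= g * lam:
        return _soft(z, lam) / (1.0 - 1.0 / g)
    return z


@njit(cache=True)
def penalty_value(b, lam, kind, alpha, shape):
    ab = abs(b)
    if kind == LASSO:
        return lam * ab
    if kind == ENET:
        return lam * (alpha * ab + 0.5 * (1.0 - alpha) * b * b)
    if kind == SCAD:
        a = shape
        if ab <= lam:
            return lam * ab
        if ab <= a * lam:
            return (2.0 * a * lam * ab - b * b - lam * lam) / (2.0 * (a - 1.0))
        return lam * lam * (a + 1.0) / 2.0
    g = shape
    if ab <= g * lam:
        return lam * ab - b * b / (2.0 * g)
    return 0.5 * g * lam * lam


@njit(cache=True)
def objective(X, y, beta, lam, kind, alpha, shape):
    n = X.shape[0]
    p = X.shape[1]
    rss = 0.0
    for i in range(n):
        pred = 0.0
        for j in range(p):
            pred += X[i, j] * beta[j]
        d = y[i] - pred
        rss += d * d
    pen = 0.0
    for j in range(p):
        pen += penalty_value(beta[j], lam, kind, alpha, shape)
    return 0.5 * rss / n + pen


@njit(cache=True)
def cd_solve(X, y, lam, kind, alpha, shape, beta, r, max_sweeps, tol, obj_out):
    """Run coordinate descent in place; returns the number of sweeps.

    ``beta`` and the residual ``r = y - X @ beta`` are updated in place
    (warm starts pass the previous solution). ``obj_out`` receives the
    penalised objective after every sweep.
    """
    n, p = X.shape
    sweeps = 0
    for s in range(max_sweeps):
        max_change = 0.0
        for j in range(p):
            bj = beta[j]
            acc = 0.0
            for i in range(n):
                acc += X[i, j] * r[i]
            z = bj + acc / n
            bn = threshold_update(z, lam, kind, alpha, shape)
            d = bn - bj
            if d != 0.0:
                for i in range(n):
                    r[i] -= d * X[i, j]
                beta[j] = bn
                ad = abs(d)
                if ad > max_change:
                    max_change = ad
        rss = 0.0
        for i in range(n):
            rss += r[i] * r[i]
        pen = 0.0
        for j in range(p):
            pen += penalty_value(beta[j], lam, kind, alpha, shape)
        obj_out[s] = 0.5 * rss / n + pen
        sweeps = s + 1
        if max_change < tol:
            break
    return sweeps


@njit(cache=True)
def cd_path_gram(G, c, lams, kind, alpha, shape, max_sweeps, tol):
    """Warm-started path via covariance updates: G = X'X/n, c = X'y/n.

    Requires unit diagonal on G (standardised columns); mathematically
    identical to the residual-updating solver but each sweep costs O(p^2)
    instead of O(n p), which dominates on long cross-validation paths.
    """
    p = c.shape[0]
    L = lams.shape[0]
    betas = np.zeros((L, p))
    beta = np.zeros(p)
    s = np.zeros(p)  # G @ beta, maintained incrementally
    for l in range(L):
        lam = lams[l]
        for _ in range(max_sweeps):
            max_change = 0.0
            for j in range(p):
                bj = beta[j]
                z = c[j] - s[j] + bj  # G[j, j] == 1
                bn = threshold_update(z, lam, kind, alpha, shape)
                d = bn - bj
                if d != 0.0:
                    for k in range(p):
                        s[k] += d * G[k, j]
                    beta[j] = bn
                    ad = abs(d)
                    if ad > max_change:
                        max_change = ad
            if max_change < tol:
                break
        for j in range(p):
            betas[l, j] = beta[j]
    return betas


@njit(cache=True)
def cd_path(X, y, lams, kind, alpha, shape, max_sweeps, tol):
    """Warm-started solutions along a decreasing lambda path; (L, p) array."""
    n, p = X.shape
    L = lams.shape[0]
    betas = np.zeros((L, p))
    beta = np.zeros(p)
    r = y.copy()
    obj = np.empty(max_sweeps)
    for l in range(L):
        cd_solve(X, y, lams[l], kind, alpha, shape, beta, r, max_sweeps, tol, obj)
        for j in range(p):
            betas[l, j] = beta[j]
    return betas
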