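"""Penalized least-squares regression with cross-validated tuning.

Fits linear models of the (log) CVD score on a taxon design matrix under
four penalty families — lasso, elastic net, SCAD and MCP — by cyclic
coordinate descent with the penalty-specific univariate update (soft,
scaled-soft, three-regime SCAD and firm thresholding respectively).
Predictors are standardised internally (mean 0, population sd 1) and
coefficients returned on the original scale; the intercept is unpenalised.

The tuning parameter is chosen by k-fold cross-validation over a log-spaced
lambda path from ``lambda_max`` (smallest lambda with an all-zero solution)
down to ``0.001 * lambda_max``, minimising mean held-out squared error.
Nonconvex fits warm-start along the decreasing path to stabilise local
minima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

from . import _cd
from .transforms import DesignMatrix

__all__ = [
    "PENALTIES",
    "PenaltySpec",
    "FitResult",
    "TuneResult",
    "fit_penalized",
    "cv_tune",
    "predict",
    "mse",
    "lambda_max",
    "lambda_path",
]

PENALTIES = ("lasso", "enet", "scad", "mcp")
_CODES = {"lasso": _cd.LASSO, "enet": _cd.ENET, "scad": _cd.SCAD, "mcp": _cd.MCP}

#: |coefficient| above which a feature counts as selected (standardised scale).
SELECTION_TOL = 1e-8


@dataclass(frozen=True)
class PenaltySpec:
    """Penalty family plus tuning and shape parameters.

    ``alpha`` is the elastic-net mixing weight (only used by ``enet``);
    ``a_scad`` and ``gamma_mcp`` are the concavity parameters at their
    canonical defaults.
    """

    kind: str
    lam: float
    alpha: float = 0.5
    a_scad: float = 3.7
    gamma_mcp: float = 3.0

    def __post_init__(self) -> None:
        if self.kind not in PENALTIES:
            raise ValueError(f"unknown penalty {self.kind!r}; expected one of {PENALTIES}")
        if not (np.isfinite(self.lam) and self.lam >= 0):
            raise ValueError(f"lambda must be finite and >= 0, got {self.lam}")
        if self.kind == "enet" and not (0 < self.alpha <= 1):
            raise ValueError(f"enet alpha must be in (0, 1], got {self.alpha}")
        if self.a_scad <= 2:
            raise ValueError(f"SCAD shape a must be > 2, got {self.a_scad}")
        if self.gamma_mcp <= 1:
            raise ValueError(f"MCP shape gamma must be > 1, got {self.gamma_mcp}")

    @property
    def shape(self) -> float:
        if self.kind == "scad":
            return self.a_scad
        if self.kind == "mcp":
            return self.gamma_mcp
        return 0.0


@dataclass
class FitResult:
    """Fitted intercept and original-scale coefficients plus the selected set."""

    feature_ids: list[str]
    intercept: float
    coefficients: np.ndarray
    lambda_chosen: float
    selected: list[str]
    signs: np.ndarray  # per feature in {-1, 0, +1}
    n_sweeps: int
    objective_path: np.ndarray | None = None


@dataclass
class TuneResult:
    """Chosen penalty plus the retained cross-validation curve."""

    spec: PenaltySpec
    lambdas: np.ndarray
    cv_mse: np.ndarray

    @property
    def lambda_chosen(self) -> float:
        return self.spec.lam


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, DesignMatrix):
        return np.asarray(X.values, dtype=float), list(X.feature_ids)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("X must be 2-D (samples x features)")
    return arr, [f"f{j}" for j in range(arr.shape[1])]


def _standardize(V: np.ndarray):
    mean = V.mean(axis=0)
    sd = V.std(axis=0)  # population sd so standardised columns have mean-square 1
    mask = sd > 0
    Xs = np.asfortranarray((V[:, mask] - mean[mask]) / sd[mask])
    return Xs, mean, sd, mask


def lambda_max(Xs: np.ndarray, yc: np.ndarray, kind: str, alpha: float = 0.5) -> float:
    """Smallest lambda at which the solution is identically zero."""
    n = Xs.shape[0]
    m = float(np.abs(Xs.T @ yc).max(initial=0.0)) / n
    if kind == "enet":
        return m / alpha
    return m


def lambda_path(lmax: float, n_lambdas: int = 100, min_ratio: float = 1e-3) -> np.ndarray:
    if lmax <= 0:
        return np.zeros(max(n_lambdas, 1))
    return np.geomspace(lmax, lmax * min_ratio, n_lambdas)


def _check_finite(V: np.ndarray, y: np.ndarray) -> None:
    if not np.isfinite(V).all() or not np.isfinite(y).all():
        raise ValueError("non-finite values in design matrix or outcome")


def fit_penalized(
    X,
    y,
    spec: PenaltySpec,
    *,
    track_objective: bool = False,
    standardize: bool = True,
    fit_intercept: bool = True,
    tol: float = 1e-7,
    max_sweeps: int = 10_000,
) -> FitResult:
    """Minimise (1/2n)||y - b0 - X b||^2 + P_lambda(b) by coordinate descent.

    Zero-variance features are excluded from the fit with their coefficient
    pinned at 0 (a warning is emitted). With ``standardize=False`` the
    caller must supply columns of mean-square one for the updates to be
    exact coordinate minimisers.
    """
    V, feature_ids = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n, p = V.shape
    if y.shape != (n,):
        raise ValueError(f"y has length {y.shape}, expected {n}")
    if n < 10:
        raise ValueError(f"need at least 10 samples to fit, got {n}")
    _check_finite(V, y)

    if standardize:
        Xs, mean, sd, mask = _standardize(V)
        if not mask.all():
            dropped = [feature_ids[j] for j in np.flatnonzero(~mask)]
            warnings.warn(f"zero-variance features excluded from fit: {dropped}", stacklevel=2)
    else:
        mask = np.ones(p, dtype=bool)
        mean = np.zeros(p)
        sd = np.ones(p)
        Xs = np.asfortranarray(V)

    ybar = y.mean() if fit_intercept else 0.0
    yc = y - ybar

    beta = np.zeros(int(mask.sum()))
    r = yc.copy()
    obj = np.empty(max_sweeps)
    code = _CODES[spec.kind]
    sweeps = _cd.cd_solve(Xs, yc, spec.lam, code, spec.alpha, spec.shape, beta, r, max_sweeps, tol, obj)

    coef = np.zeros(p)
    coef[mask] = beta / sd[mask] if standardize else beta
    intercept = ybar - float(coef @ mean) if standardize else ybar

    signs_std = np.zeros(p, dtype=int)
    sel_mask = np.zeros(p, dtype=bool)
    sel_mask[mask] = np.abs(beta) > SELECTION_TOL
    signs_std[sel_mask] = np.sign(coef[sel_mask]).astype(int)
    selected = [feature_ids[j] for j in np.flatnonzero(sel_mask)]

    return FitResult(
        feature_ids=feature_ids,
        intercept=intercept,
        coefficients=coef,
        lambda_chosen=spec.lam,
        selected=selected,
        signs=signs_std,
        n_sweeps=sweeps,
        objective_path=obj[:sweeps].copy() if track_objective else None,
    )


def _path_predictions(Vtr, ytr, Vte, code, alpha, shape, lams, tol, max_sweeps):
    """Destandardised held-out predictions for every lambda; (n_te, L)."""
    mean = Vtr.mean(axis=0)
    sd = Vtr.std(axis=0)
    mask = sd > 0
    Xs = (Vtr[:, mask] - mean[mask]) / sd[mask]
    ybar = ytr.mean()
    yc = ytr - ybar
    n = Xs.shape[0]
    G = np.ascontiguousarray(Xs.T @ Xs / n)
    c = Xs.T @ yc / n
    betas = _cd.cd_path_gram(G, c, lams, code, alpha, shape, max_sweeps, tol)
    coef = betas / sd[mask]  # (L, p_mask) on original scale
    inter = ybar - coef @ mean[mask]
    return Vte[:, mask] @ coef.T + inter[None, :]


def cv_tune(
    X,
    y,
    kind: str,
    folds: int = 10,
    seed: int = 0,
    *,
    alpha: float = 0.5,
    a_scad: float = 3.7,
    gamma_mcp: float = 3.0,
    n_lambdas: int = 100,
    min_ratio: float = 1e-3,
    tol: float = 1e-7,
    max_sweeps: int = 10_000,
) -> TuneResult:
    """Pick lambda by k-fold CV on a log-spaced path from lambda_max.

    Folds are assigned by a seeded shuffle; the lambda minimising the mean
    held-out squared error is returned (largest lambda wins ties). The full
    CV curve is retained on the result.
    """
    V, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n = V.shape[0]
    if folds > n:
        raise ValueError(f"folds ({folds}) cannot exceed the number of samples ({n})")
    _check_finite(V, y)

    ref = PenaltySpec(kind=kind, lam=0.0, alpha=alpha, a_scad=a_scad, gamma_mcp=gamma_mcp)
    mean = V.mean(axis=0)
    sd = V.std(axis=0)
    mask = sd > 0
    Xs_full = (V[:, mask] - mean[mask]) / sd[mask]
    lmax = lambda_max(Xs_full, y - y.mean(), kind, alpha)
    lams = lambda_path(lmax, n_lambdas, min_ratio)

    code = _CODES[kind]
    sq_err = np.zeros(len(lams))
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    for tr_idx, te_idx in kf.split(V):
        preds = _path_predictions(
            V[tr_idx], y[tr_idx], V[te_idx], code, alpha, ref.shape, lams, tol, max_sweeps
        )
        sq_err += ((preds - y[te_idx][:, None]) ** 2).sum(axis=0)
    cv_mse = sq_err / n
    best = int(np.argmin(cv_mse))  # path is decreasing, so first min = largest lambda
    spec = PenaltySpec(kind=kind, lam=float(lams[best]), alpha=alpha, a_scad=a_scad, gamma_mcp=gamma_mcp)
    return TuneResult(spec=spec, lambdas=lams, cv_mse=cv_mse)


def predict(fit: FitResult, X) -> np.ndarray:
    """Linear predictions b0 + X b; feature ids must align when tagged."""
    V, ids = _as_matrix(X)
    if isinstance(X, DesignMatrix) and ids != fit.feature_ids:
        mismatch = set(ids).symmetric_difference(fit.feature_ids)
        raise ValueError(f"feature ids do not align with the fit: {sorted(mismatch)}")
    if V.shape[1] != len(fit.coefficients):
        raise ValueError(
            f"X has {V.shape[1]} features, fit has {len(fit.coefficients)}"
        )
    return fit.intercept + V @ fit.coefficients


def mse(pred, y) -> float:
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(y, dtype=float)
    if pred.shape != y.shape:
        raise ValueError("prediction/outcome length mismatch")
    return float(np.mean((pred - y) ** 2))
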