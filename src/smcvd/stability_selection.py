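"""Stability selection over repeated train/test splits.

The cohort is split 50 times (by default) into an 80% training and 20% test
portion. Within each split the same partition is reused for every penalty
family and predictor transform; per cell a lambda is tuned by 10-fold CV on
the training portion, the model refitted at that lambda, and the selected
feature set, coefficient signs and test-set MSE recorded. Features selected
in at least 80% of splits by *all* requested methods under a transform are
"pertinent" for that transform; the intersection across transforms is the
common marker set. Sign tallies over splits give each marker a direction
call (risk-increasing / risk-decreasing).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .penalized_models import PENALTIES, cv_tune, fit_penalized, mse, predict
from .transforms import DesignMatrix

__all__ = [
    "SplitPlan",
    "StabilityReport",
    "run_stability",
    "pertinent_features",
    "sign_summary",
    "compare_mse",
]


@dataclass(frozen=True)
class SplitPlan:
    """Deterministic plan for the repeated random 80/20 splits."""

    n_splits: int = 50
    train_fraction: float = 0.8
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError(f"train_fraction must be in (0, 1), got {self.train_fraction}")
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")

    @property
    def split_seeds(self) -> np.ndarray:
        """One derived 31-bit seed per split, a pure function of master_seed."""
        ss = np.random.SeedSequence(self.master_seed)
        return (ss.generate_state(self.n_splits) % (2**31)).astype(np.int64)


@dataclass
class StabilityReport:
    """Selection frequencies, sign tallies and test MSEs per method x transform."""

    feature_ids: list[str]
    methods: list[str]
    transforms: list[str]
    n_splits: int
    # arrays indexed [transform, method, feature]
    frequency: np.ndarray
    sign_counts: np.ndarray  # [..., 3] = (n_positive, n_negative, n_zero)
    # [split, transform, method]
    mse_table: np.ndarray
    master_seed: int = 0

    def frequency_frame(self) -> pd.DataFrame:
        rows = []
        for t, tr in enumerate(self.transforms):
            for m, me in enumerate(self.methods):
                for f, fid in enumerate(self.feature_ids):
                    rows.append((fid, me, tr, self.frequency[t, m, f]))
        return pd.DataFrame(rows, columns=["feature", "method", "transform", "frequency"])

    def sign_frame(self) -> pd.DataFrame:
        rows = []
        for t, tr in enumerate(self.transforms):
            for m, me in enumerate(self.methods):
                for f, fid in enumerate(self.feature_ids):
                    npos, nneg, nzero = self.sign_counts[t, m, f]
                    rows.append((fid, me, tr, int(npos), int(nneg), int(nzero)))
        return pd.DataFrame(
            rows, columns=["feature", "method", "transform", "n_positive", "n_negative", "n_zero"]
        )

    def mse_frame(self) -> pd.DataFrame:
        rows = []
        for s in range(self.n_splits):
            for t, tr in enumerate(self.transforms):
                for m, me in enumerate(self.methods):
                    rows.append((s, me, tr, self.mse_table[s, t, m]))
        return pd.DataFrame(rows, columns=["split", "method", "transform", "test_mse"])

    def write_tables(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.frequency_frame().to_csv(directory / "selection_frequency.tsv", sep="\t", index=False)
        self.sign_frame().to_csv(directory / "sign_counts.tsv", sep="\t", index=False)
        self.mse_frame().to_csv(directory / "test_mse.tsv", sep="\t", index=False)


def run_stability(
    X_by_transform: dict[str, DesignMatrix],
    y,
    plan: SplitPlan,
    methods=PENALTIES,
    cv_folds: int = 10,
    *,
    enet_alpha: float = 0.5,
    n_lambdas: int = 100,
) -> StabilityReport:
    """Run the full splits x methods x transforms resampling.

    All transforms must share sample order with ``y``; the identical 80/20
    partition is reused across methods and transforms within a split so the
    per-split MSE comparison is paired.
    """
    methods = list(methods)
    unknown = set(methods) - set(PENALTIES)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    transforms = list(X_by_transform)
    y = np.asarray(y, dtype=float)
    n = len(y)
    feature_ids = None
    for tag, X in X_by_transform.items():
        if X.n_samples != n:
            raise ValueError(f"transform {tag!r} has {X.n_samples} samples, y has {n}")
        if feature_ids is None:
            feature_ids = list(X.feature_ids)
        elif list(X.feature_ids) != feature_ids:
            raise ValueError("all transforms must share the same feature ids")
    n_train = int(round(plan.train_fraction * n))
    if n_train < cv_folds:
        raise ValueError(
            f"training portion ({n_train}) smaller than cv_folds ({cv_folds}); nothing fitted"
        )
    if n_train >= n:
        raise ValueError("train_fraction leaves no test samples")

    T, M, F = len(transforms), len(methods), len(feature_ids)
    sel = np.zeros((plan.n_splits, T, M, F), dtype=bool)
    signs = np.zeros((plan.n_splits, T, M, F), dtype=np.int8)
    mses = np.zeros((plan.n_splits, T, M))

    for s, split_seed in enumerate(plan.split_seeds):
        rng = np.random.default_rng(split_seed)
        perm = rng.permutation(n)
        tr_idx, te_idx = perm[:n_train], perm[n_train:]
        cv_seed = int(split_seed % (2**31))
        for t, tag in enumerate(transforms):
            V = X_by_transform[tag].values
            Vtr, Vte = V[tr_idx], V[te_idx]
            ytr, yte = y[tr_idx], y[te_idx]
            for m, kind in enumerate(methods):
                tune = cv_tune(
                    Vtr, ytr, kind, folds=cv_folds, seed=cv_seed,
                    alpha=enet_alpha, n_lambdas=n_lambdas,
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # all-zero training features -> not selected
                    fit = fit_penalized(Vtr, ytr, tune.spec)
                sel[s, t, m] = fit.signs != 0
                signs[s, t, m] = fit.signs
                mses[s, t, m] = mse(predict(fit, Vte), yte)

    frequency = sel.mean(axis=0).astype(float)
    sign_counts = np.stack(
        [(signs > 0).sum(axis=0), (signs < 0).sum(axis=0), (signs == 0).sum(axis=0)],
        axis=-1,
    )
    return StabilityReport(
        feature_ids=feature_ids,
        methods=methods,
        transforms=transforms,
        n_splits=plan.n_splits,
        frequency=frequency,
        sign_counts=sign_counts,
        mse_table=mses,
        master_seed=plan.master_seed,
    )


def pertinent_features(
    report: StabilityReport, threshold: float = 0.8, mode: str = "all"
) -> dict:
    """Apply the selection-frequency rule and the cross-transform Venn logic.

    ``mode='all'``: a feature is pertinent for a transform when its
    frequency reaches ``threshold`` in every method under that transform
    (the default reading); ``mode='pooled'`` uses the mean frequency over
    methods instead. Returns per-transform sets, their intersection
    (``common``) and the per-transform complements (``specific``).
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if mode not in ("all", "pooled"):
        raise ValueError(f"mode must be 'all' or 'pooled', got {mode!r}")
    per_transform: dict[str, set[str]] = {}
    for t, tr in enumerate(report.transforms):
        if mode == "all":
            ok = (report.frequency[t] >= threshold).all(axis=0)
        else:
            ok = report.frequency[t].mean(axis=0) >= threshold
        per_transform[tr] = {fid for f, fid in enumerate(report.feature_ids) if ok[f]}
    common = set.intersection(*per_transform.values()) if per_transform else set()
    specific = {tr: s - common for tr, s in per_transform.items()}
    return {"per_transform": per_transform, "common": common, "specific": specific}


def _direction(npos: int, nneg: int) -> str:
    if npos == nneg:
        return "mixed"
    return "risk-increasing" if npos > nneg else "risk-decreasing"


def sign_summary(report: StabilityReport) -> pd.DataFrame:
    """Sign tallies per (feature, method, transform) with a direction call.

    The call is the majority over nonzero counts: risk-increasing when
    positives dominate, risk-decreasing when negatives dominate, mixed on a
    tie (including all-zero).
    """
    df = report.sign_frame()
    df["direction"] = [
        _direction(p, q) for p, q in zip(df["n_positive"], df["n_negative"])
    ]
    return df


def compare_mse(report: StabilityReport) -> dict:
    """Median/IQR of test MSEs per cell plus paired transform comparisons.

    The transform comparison uses per-split MSE differences (same partition
    in both transforms) and a two-sided Wilcoxon signed-rank test per
    method; all-zero differences give p = 1.
    """
    rows = []
    for t, tr in enumerate(report.transforms):
        for m, me in enumerate(report.methods):
            v = report.mse_table[:, t, m]
            rows.append(
                {
                    "method": me,
                    "transform": tr,
                    "median": float(np.median(v)),
                    "q1": float(np.percentile(v, 25)),
                    "q3": float(np.percentile(v, 75)),
                }
            )
    summary = pd.DataFrame(rows)
    pairwise = []
    if len(report.transforms) == 2:
        t0, t1 = 0, 1
        for m, me in enumerate(report.methods):
            diff = report.mse_table[:, t0, m] - report.mse_table[:, t1, m]
            if np.allclose(diff, 0.0):
                pval = 1.0
            else:
                pval = float(stats.wilcoxon(diff).pvalue)
            pairwise.append(
                {
                    "method": me,
                    "transform_a": report.transforms[t0],
                    "transform_b": report.transforms[t1],
                    "median_diff": float(np.median(diff)),
                    "wilcoxon_p": pval,
                }
            )
    return {"summary": summary, "pairwise": pd.DataFrame(pairwise)}


def write_pertinent_json(pertinent: dict, path) -> None:
    payload = {
        "per_transform": {k: sorted(v) for k, v in pertinent["per_transform"].items()},
        "common": sorted(pertinent["common"]),
        "specific": {k: sorted(v) for k, v in pertinent["specific"].items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
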