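"""Alpha diversity, Bray-Curtis dissimilarity, ANOSIM and Mann-Whitney.

All statistics are computed from their standard formulas on raw counts:

* observed richness — number of taxa with a positive count;
* Shannon — ``-sum(p ln p)`` over nonzero proportions;
* Simpson — ``1 - sum(p^2)``;
* Chao1 — bias-corrected ``S_obs + F1 (F1 - 1) / (2 (F2 + 1))`` from
  singleton (F1) and doubleton (F2) counts (the classical ``F1^2 / (2 F2)``
  form is available by flag);
* Bray-Curtis — ``sum|x - y| / sum(x + y)``;
* ANOSIM — rank-based ``R = (rb - rw) / (n(n-1)/4)`` over midranked
  pairwise distances, with an add-one permutation p-value;
* Mann-Whitney U — midranks for ties, exact enumeration for small samples,
  otherwise a tie-corrected normal approximation with continuity correction.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .feature_io import FeatureTable

__all__ = [
    "ALPHA_INDICES",
    "DistanceMatrix",
    "alpha_diversity",
    "bray_curtis",
    "anosim",
    "mann_whitney",
]

logger = logging.getLogger(__name__)

ALPHA_INDICES = ("observed", "chao1", "shannon", "simpson")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape must match the labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.abs(np.diag(self.values)).max(initial=0.0) != 0.0:
            raise ValueError("distance matrix diagonal must be exactly zero")
        if (self.values < 0).any():
            raise ValueError("distances must be nonnegative")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="sample")


def _alpha_one(counts: np.ndarray, index: str, chao1_bias_corrected: bool) -> float:
    counts = counts[counts > 0]
    if counts.size == 0:
        logger.warning("empty sample: %s index set to 0", index)
        return 0.0
    if index == "observed":
        return float(counts.size)
    if index == "shannon":
        p = counts / counts.sum()
        return float(-(p * np.log(p)).sum())
    if index == "simpson":
        p = counts / counts.sum()
        return float(1.0 - (p**2).sum())
    # chao1
    s_obs = counts.size
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if chao1_bias_corrected:
        return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))
    if f2 > 0:
        return float(s_obs + f1 * f1 / (2.0 * f2))
    return float(s_obs + f1 * (f1 - 1) / 2.0)


def alpha_diversity(
    table: FeatureTable, index: str, *, chao1_bias_corrected: bool = True
) -> pd.Series:
    """Per-sample alpha diversity for one index."""
    if index not in ALPHA_INDICES:
        raise ValueError(f"unknown index {index!r}; expected one of {ALPHA_INDICES}")
    vals = [
        _alpha_one(table.counts[:, s], index, chao1_bias_corrected)
        for s in range(table.n_samples)
    ]
    return pd.Series(vals, index=table.sample_ids, name=index)


def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities on raw counts.

    A pair of all-zero samples gets distance 0 with a warning.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    C = table.counts.T.astype(float)  # samples x taxa
    n = C.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = (C[i] + C[j]).sum()
            if denom == 0:
                logger.warning(
                    "both samples all-zero (%s, %s); Bray-Curtis set to 0",
                    table.sample_ids[i],
                    table.sample_ids[j],
                )
                d = 0.0
            else:
                d = np.abs(C[i] - C[j]).sum() / denom
            D[i, j] = D[j, i] = d
    return DistanceMatrix(labels=list(table.sample_ids), values=D)


def _anosim_r(ranks: np.ndarray, within: np.ndarray, n: int) -> float:
    # Clarke's divisor n(n-1)/4 bounds R in [-1, 1]
    rb = ranks[~within].mean()
    rw = ranks[within].mean()
    return (rb - rw) / (n * (n - 1) / 4.0)


def anosim(
    dist: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int = 0,
    *,
    exhaustive: bool = False,
) -> tuple[float, float]:
    """ANOSIM R and its permutation p-value.

    ``exhaustive=True`` enumerates every distinct relabelling (only feasible
    for small designs) instead of sampling ``n_perm`` seeded permutations.
    """
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    if (counts < 2).any():
        small = labels[counts < 2]
        raise ValueError(f"every group needs >= 2 members; too small: {list(small)}")
    n = len(groups)
    if n != len(dist.labels):
        raise ValueError("group labels must match the distance matrix size")
    iu = np.triu_indices(n, k=1)
    d = dist.values[iu]
    ranks = rankdata(d)  # midranks
    same = groups[iu[0]] == groups[iu[1]]
    r_obs = _anosim_r(ranks, same, n)

    if exhaustive:
        # enumerate every distinct relabelling (multiset permutations)
        r_perm = []
        for combo in _distinct_assignments(groups):
            w = combo[iu[0]] == combo[iu[1]]
            r_perm.append(_anosim_r(ranks, w, n))
        r_perm = np.asarray(r_perm)
        p = float((r_perm >= r_obs - 1e-12).mean())
        return float(r_obs), p

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        g = groups[rng.permutation(n)]
        w = g[iu[0]] == g[iu[1]]
        if _anosim_r(ranks, w, n) >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(r_obs), float(p)


def _distinct_assignments(groups: np.ndarray):
    """Yield every distinct group labelling (multiset permutations)."""
    n = len(groups)
    labels, counts = np.unique(groups, return_counts=True)

    def rec(positions, remaining):
        if len(remaining) == 1:
            out = np.empty(n, dtype=groups.dtype)
            out[list(positions)] = remaining[0][0]
            yield out
            return
        label, k = remaining[0]
        for combo in itertools.combinations(positions, k):
            rest = [p for p in positions if p not in set(combo)]
            for out in rec(rest, remaining[1:]):
                out[list(combo)] = label
                yield out

    yield from rec(list(range(n)), list(zip(labels, counts)))


def _mw_u(x: np.ndarray, y: np.ndarray) -> float:
    n1 = len(x)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    return r1 - n1 * (n1 + 1) / 2.0


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U (for ``x``) with a two-sided p-value.

    Exact enumeration of all assignments when ``n1 + n2 <= 12``; otherwise
    a normal approximation with tie-corrected variance and continuity
    correction. Identical constant samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = len(x), len(y)
    u = _mw_u(x, y)
    mu = n1 * n2 / 2.0

    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(u), 1.0

    if n1 + n2 <= 12:
        dev_obs = abs(u - mu)
        idx = range(n1 + n2)
        total = 0
        hits = 0
        for combo in itertools.combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(combo)] = True
            u_p = _mw_u(pooled[mask], pooled[~mask])
            total += 1
            if abs(u_p - mu) >= dev_obs - 1e-12:
                hits += 1
        return float(u), hits / total

    # normal approximation with tie correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    nt = n1 + n2
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (nt * (nt - 1))
    var = n1 * n2 / 12.0 * ((nt + 1) - tie_term)
    if var == 0:
        return float(u), 1.0
    z = (abs(u - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * (1.0 - _norm_cdf(z)))
    return float(u), float(p)


def _norm_cdf(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))
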