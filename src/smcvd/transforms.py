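"""Predictor and outcome transformations for the regression stage.

Two predictor codings of the taxon table are used: presence/absence
(``binary``) and the arcsine-square-root of relative abundance (``arcsin``),
the standard variance stabiliser for proportions. The percent CVD score is
log-transformed (natural log) before modelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .feature_io import AbundanceMatrix, FeatureTable

__all__ = ["DesignMatrix", "binary_transform", "arcsin_transform", "log_outcome"]

TRANSFORMS = ("binary", "arcsin")


@dataclass
class DesignMatrix:
    """Samples x features predictor matrix with a transform tag."""

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    transform_tag: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("design matrix must be 2-D (samples x features)")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError("design matrix shape does not match sample/feature ids")
        if self.transform_tag == "binary":
            if not np.isin(self.values, (0.0, 1.0)).all():
                raise ValueError("binary design must contain only 0/1")
        elif self.transform_tag == "arcsin":
            if self.values.min(initial=0.0) < 0 or self.values.max(initial=0.0) > np.pi / 2 + 1e-12:
                raise ValueError("arcsin design must lie in [0, pi/2]")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def binary_transform(table: FeatureTable) -> DesignMatrix:
    """Presence/absence coding: 1 where the count is positive."""
    values = (table.counts > 0).astype(float).T
    return DesignMatrix(
        values=values,
        feature_ids=list(table.taxon_ids),
        sample_ids=list(table.sample_ids),
        transform_tag="binary",
    )


def arcsin_transform(abund: AbundanceMatrix) -> DesignMatrix:
    """arcsin(sqrt(p)) of per-sample proportions; domain-checked to [0, 1]."""
    p = np.asarray(abund.values, dtype=float)
    if p.min(initial=0.0) < -1e-12 or p.max(initial=0.0) > 1.0 + 1e-12:
        bad = p[(p < -1e-12) | (p > 1.0 + 1e-12)].flat[0]
        raise ValueError(f"proportions must lie in [0, 1]; got {bad}")
    values = np.arcsin(np.sqrt(np.clip(p, 0.0, 1.0))).T
    return DesignMatrix(
        values=values,
        feature_ids=list(abund.taxon_ids),
        sample_ids=list(abund.sample_ids),
        transform_tag="arcsin",
    )


def log_outcome(scores, eps: float = 1e-6) -> np.ndarray:
    """Natural log of the percent score, floored at ``eps`` to stay finite."""
    s = np.asarray(scores, dtype=float)
    if (s < 0).any():
        raise ValueError("scores must be nonnegative")
    return np.log(np.maximum(s, eps))
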