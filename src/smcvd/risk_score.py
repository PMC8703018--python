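"""Sex-specific 10-year cardiovascular disease (CVD) risk scoring and stratification.

The risk equation is the Cox-model survival form

    p_hat = 1 - S0 ** exp( sum_i beta_i * g_i(x_i) - sum_i beta_i * xbar_i )

where ``S0`` is the sex-specific baseline survival at the 10-year horizon,
``beta_i`` the log-hazard-ratio of the i-th risk factor, ``g_i`` the natural
log for factors flagged ``log`` and the identity otherwise, and ``xbar_i``
the factor's reference mean. Binary factors (smoking, diabetes, treated
hypertension) contribute their coefficient when the flag is set. Scores are
expressed in percent and stratified into low (<10), moderate (10-20,
inclusive on both ends) and high (>20) risk groups.

Coefficient sets live entirely in configuration (:func:`load_risk_model`);
the shipped default (:func:`default_risk_model`) is the published sex-specific
general-CVD office-based function with log age / lipids / systolic BP and
binary smoking and diabetes terms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ClinicalRecord",
    "RiskTerm",
    "SexModel",
    "RiskModel",
    "RiskResult",
    "RiskConfigError",
    "compute_risk",
    "stratify",
    "score_cohort",
    "load_risk_model",
    "default_risk_model",
    "CLINICAL_COLUMNS",
]

logger = logging.getLogger(__name__)

#: mmol/L -> mg/dL conversion for cholesterol fractions.
MMOL_TO_MGDL = 38.67

GROUPS = ("LR", "MR", "HR")

#: Fixed column order of a clinical table on disk.
CLINICAL_COLUMNS = [
    "subject_id",
    "sex",
    "age",
    "total_chol",
    "hdl",
    "sbp",
    "bp_treated",
    "smoker",
    "diabetic",
]

_CONTINUOUS_FACTORS = {
    "age": ("age", 1.0),
    "total_chol": ("total_chol", 1.0),
    "hdl": ("hdl", 1.0),
    "sbp": ("sbp", 1.0),
    "total_chol_mgdl": ("total_chol", MMOL_TO_MGDL),
    "hdl_mgdl": ("hdl", MMOL_TO_MGDL),
}
_BINARY_FACTORS = {"smoker", "diabetic", "bp_treated"}


class RiskConfigError(ValueError):
    """A risk-model configuration is missing or inconsistent."""


@dataclass(frozen=True)
class ClinicalRecord:
    """One subject's risk-factor values.

    Units: age in years, cholesterol fractions in mmol/L, systolic blood
    pressure in mmHg; ``bp_treated``/``smoker``/``diabetic`` are flags.
    """

    subject_id: str
    sex: str
    age: float
    total_chol: float
    hdl: float
    sbp: float
    bp_treated: bool = False
    smoker: bool = False
    diabetic: bool = False

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        for name in ("age", "total_chol", "hdl", "sbp"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(
                    f"{name} must be finite and > 0 for subject {self.subject_id!r}, got {v!r}"
                )


@dataclass(frozen=True)
class RiskTerm:
    """One additive term of the risk equation's linear predictor."""

    name: str
    factor: str
    beta: float
    mean: float = 0.0
    log: bool = False
    #: optional gating flag: "bp_treated" (active when set) or "!bp_treated".
    when: str | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.beta):
            raise RiskConfigError(f"term {self.name!r}: beta must be finite")
        known = set(_CONTINUOUS_FACTORS) | _BINARY_FACTORS
        if self.factor not in known:
            raise RiskConfigError(f"term {self.name!r}: unknown factor {self.factor!r}")


@dataclass(frozen=True)
class SexModel:
    """Baseline survival plus terms for one sex.

    ``mean_sum`` is the aggregate sum(beta_i * xbar_i); when given it
    overrides the per-term ``mean`` values (which then serve documentation
    only).
    """

    s0: float
    terms: tuple[RiskTerm, ...]
    mean_sum: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.s0 <= 1.0):
            raise RiskConfigError(f"s0 must be in (0, 1], got {self.s0}")
        if not self.terms:
            raise RiskConfigError("a sex model needs at least one term")

    @property
    def mean_offset(self) -> float:
        if self.mean_sum is not None:
            return float(self.mean_sum)
        return float(sum(t.beta * t.mean for t in self.terms))


@dataclass(frozen=True)
class RiskModel:
    """Sex-specific risk-equation parameterisation at a 10-year horizon."""

    sexes: dict[str, SexModel]
    horizon_years: int = 10

    def for_sex(self, sex: str) -> SexModel:
        try:
            return self.sexes[sex]
        except KeyError:
            raise RiskConfigError(f"risk model has no coefficient set for sex {sex!r}") from None


@dataclass(frozen=True)
class RiskResult:
    score: float
    group: str


def _term_active(term: RiskTerm, record: ClinicalRecord) -> bool:
    if term.when is None:
        return True
    flag = term.when.lstrip("!")
    value = bool(getattr(record, flag))
    return (not value) if term.when.startswith("!") else value


def _term_value(term: RiskTerm, record: ClinicalRecord) -> float:
    if term.factor in _BINARY_FACTORS:
        return 1.0 if getattr(record, term.factor) else 0.0
    attr, scale = _CONTINUOUS_FACTORS[term.factor]
    x = float(getattr(record, attr)) * scale
    if term.log:
        if x <= 0:
            raise ValueError(f"cannot take log of nonpositive factor {term.factor!r} (value {x})")
        return math.log(x)
    return x


def compute_risk(record: ClinicalRecord, model: RiskModel) -> float:
    """10-year CVD risk for one subject, in percent (range [0, 100))."""
    sex_model = model.for_sex(record.sex)
    lin = 0.0
    for term in sex_model.terms:
        if _term_active(term, record):
            lin += term.beta * _term_value(term, record)
    lin -= sex_model.mean_offset
    p_hat = 1.0 - sex_model.s0 ** math.exp(lin)
    return 100.0 * p_hat


def stratify(score: float) -> str:
    """Map a percent score onto the LR / MR / HR partition of [0, inf)."""
    if not np.isfinite(score) or score < 0:
        raise ValueError(f"score must be finite and >= 0, got {score!r}")
    if score < 10.0:
        return "LR"
    if score <= 20.0:
        return "MR"
    return "HR"


def _coerce_clinical(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    out = df.copy()
    for col in ("bp_treated", "smoker", "diabetic"):
        out[col] = out[col].astype(bool)
    bad = []
    for _, row in out.iterrows():
        try:
            ClinicalRecord(
                subject_id=str(row["subject_id"]),
                sex=row["sex"],
                age=float(row["age"]),
                total_chol=float(row["total_chol"]),
                hdl=float(row["hdl"]),
                sbp=float(row["sbp"]),
                bp_treated=bool(row["bp_treated"]),
                smoker=bool(row["smoker"]),
                diabetic=bool(row["diabetic"]),
            )
        except (ValueError, TypeError):
            bad.append(str(row["subject_id"]))
    if bad:
        raise ValueError(f"invalid clinical rows for subjects: {bad}")
    return out


def score_frame(df: pd.DataFrame, model: RiskModel) -> np.ndarray:
    """Vectorised risk scores (percent) for a validated clinical table."""
    n = len(df)
    lin = np.zeros(n)
    s0 = np.empty(n)
    for sex in ("male", "female"):
        mask = (df["sex"] == sex).to_numpy()
        if not mask.any():
            continue
        sex_model = model.for_sex(sex)
        s0[mask] = sex_model.s0
        acc = np.zeros(mask.sum())
        for term in sex_model.terms:
            if term.factor in _BINARY_FACTORS:
                val = df.loc[mask, term.factor].to_numpy(dtype=float)
            else:
                attr, scale = _CONTINUOUS_FACTORS[term.factor]
                val = df.loc[mask, attr].to_numpy(dtype=float) * scale
                if term.log:
                    if np.any(val <= 0):
                        raise ValueError(f"cannot take log of nonpositive factor {term.factor!r}")
                    val = np.log(val)
            if term.when is not None:
                flag = df.loc[mask, term.when.lstrip("!")].to_numpy(dtype=bool)
                active = ~flag if term.when.startswith("!") else flag
            else:
                active = np.ones(mask.sum(), dtype=bool)
            acc += np.where(active, term.beta * val, 0.0)
        lin[mask] = acc - sex_model.mean_offset
    return 100.0 * (1.0 - s0 ** np.exp(lin))


def score_cohort(clinical: pd.DataFrame, model: RiskModel) -> pd.DataFrame:
    """Score every subject; returns subject_id, score (percent) and group.

    An empty table yields an empty result with a warning; any invalid row
    aborts with the offending subject ids listed.
    """
    if len(clinical) == 0:
        logger.warning("score_cohort called on an empty clinical table")
        return pd.DataFrame(columns=["subject_id", "score", "group"])
    df = _coerce_clinical(clinical)
    scores = score_frame(df, model)
    groups = [stratify(s) for s in scores]
    counts = {g: groups.count(g) for g in GROUPS}
    logger.info("risk group counts: %s", counts)
    return pd.DataFrame(
        {"subject_id": df["subject_id"].astype(str).to_numpy(), "score": scores, "group": groups}
    )


def _parse_sex_block(block: dict) -> SexModel:
    try:
        terms = tuple(
            RiskTerm(
                name=t["name"],
                factor=t["factor"],
                beta=float(t["beta"]),
                mean=float(t.get("mean", 0.0)),
                log=bool(t.get("log", False)),
                when=t.get("when"),
            )
            for t in block["terms"]
        )
        return SexModel(s0=float(block["s0"]), terms=terms, mean_sum=block.get("mean_sum"))
    except (KeyError, TypeError) as exc:
        raise RiskConfigError(f"malformed risk-model block: {exc}") from exc


def load_risk_model(source) -> RiskModel:
    """Load a risk model from a YAML path or an already-parsed mapping."""
    if isinstance(source, dict):
        raw = source
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or not raw:
        raise RiskConfigError("risk-model config must be a mapping of per-sex blocks")
    sexes = {sex: _parse_sex_block(block) for sex, block in raw.items()}
    return RiskModel(sexes=sexes)


def default_risk_model() -> RiskModel:
    """The bundled sex-specific general-CVD function (10-year horizon)."""
    ref = resources.files("smcvd.data").joinpath("framingham_general_cvd.yaml")
    raw = yaml.safe_load(ref.read_text())
    return load_risk_model(raw)
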