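"""Seeded synthetic cohorts with planted taxon-outcome effects.

The generator emulates the structure the downstream analysis assumes: a
clinical covariate table whose computed 10-year CVD risk scores land in a
target low/moderate/high-risk mix (default 84% / 11% / 5%), a genus-level
Dirichlet-multinomial count table with a few dominant genera, and a handful
of planted taxa whose presence (``binary`` mechanism) or arcsin-sqrt
relative abundance (``continuous`` mechanism) shifts the log CVD score by a
known signed coefficient. The remaining taxa are pure compositional noise.

All randomness flows from ``SyntheticSpec.seed``; identical specs produce
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .feature_io import FeatureTable, write_feature_table
from .risk_score import CLINICAL_COLUMNS, RiskModel, default_risk_model, score_frame, stratify

__all__ = ["SyntheticSpec", "SyntheticTruth", "Cohort", "generate_cohort", "write_cohort", "read_clinical"]

GROUPS = ("LR", "MR", "HR")

#: Stratum-conditional clinical covariate distributions. Age / cholesterol /
#: HDL means follow the published low/moderate/high-risk group profiles of a
#: large adult cohort; SBP and the flag rates rise with risk. Values are
#: (mean, sd) for Normals, a probability for flags.
_STRATUM_PARAMS = {
    "LR": dict(age=(35.0, 10.0), chol=(4.9, 0.9), hdl=(1.43, 0.35), sbp=(118.0, 12.0),
               bp_treated=0.05, smoker=0.12, diabetic=0.06),
    "MR": dict(age=(51.0, 7.0), chol=(5.4, 1.0), hdl=(1.19, 0.30), sbp=(132.0, 13.0),
               bp_treated=0.25, smoker=0.25, diabetic=0.30),
    "HR": dict(age=(57.0, 8.0), chol=(5.4, 1.2), hdl=(1.12, 0.29), sbp=(142.0, 15.0),
               bp_treated=0.40, smoker=0.35, diabetic=0.55),
}

#: Plausible oral genera used to synthesise Greengenes-style lineages.
_GENUS_POOL = [
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", "Prevotella"),
    ("Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus"),
    ("Proteobacteria", "Betaproteobacteria", "Neisseriales", "Neisseriaceae", "Neisseria"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Veillonellaceae", "Veillonella"),
    ("Actinobacteria", "Actinobacteria", "Actinomycetales", "Actinomycetaceae", "Actinomyces"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Porphyromonadaceae", "Porphyromonas"),
    ("Firmicutes", "Bacilli", "Lactobacillales", "Carnobacteriaceae", "Granulicatella"),
    ("Proteobacteria", "Gammaproteobacteria", "Pasteurellales", "Pasteurellaceae", "Haemophilus"),
    ("Actinobacteria", "Actinobacteria", "Actinomycetales", "Micrococcaceae", "Rothia"),
    ("Fusobacteria", "Fusobacteriia", "Fusobacteriales", "Fusobacteriaceae", "Fusobacterium"),
    ("Bacteroidetes", "Flavobacteriia", "Flavobacteriales", "Flavobacteriaceae", "Capnocytophaga"),
    ("Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", "Lactobacillus"),
    ("Proteobacteria", "Deltaproteobacteria", "Desulfobacterales", "Desulfobulbaceae", "Desulfobulbus"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Clostridiaceae", "Clostridium"),
    ("Fusobacteria", "Fusobacteriia", "Fusobacteriales", "Leptotrichiaceae", "Leptotrichia"),
    ("Firmicutes", "Bacilli", "Gemellales", "Gemellaceae", "Gemella"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Tissierellaceae", "Tissierella"),
    ("Proteobacteria", "Gammaproteobacteria", "Cardiobacteriales", "Cardiobacteriaceae", "Cardiobacterium"),
    ("Actinobacteria", "Coriobacteriia", "Coriobacteriales", "Coriobacteriaceae", "Atopobium"),
    ("Spirochaetes", "Spirochaetia", "Spirochaetales", "Spirochaetaceae", "Treponema"),
]

#: Steepness of the logistic linking baseline log score to presence of a
#: binary-mechanism taxon.
_PRESENCE_SLOPE = 1.5

#: Precision multiplier for continuous-mechanism taxa: their proportion gets
#: a Beta marginal with the same mean as the Dirichlet background but a
#: tenth of the precision, i.e. far more between-subject spread — taxa whose
#: abundance tracks host phenotype are overdispersed relative to the neutral
#: compositional background.
_CONTINUOUS_DISPERSION = 0.1


def _default_concentration(n_taxa: int, total: float = 30.0, decay: float = 0.85) -> np.ndarray:
    w = decay ** np.arange(n_taxa)
    return total * w / w.sum()


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic cohort.

    ``effect_sizes`` are signed shifts of the log CVD score, one per planted
    taxon (binary-mechanism taxa first, then continuous); ``noise_sd`` is
    the residual sd of the log score.
    """

    n_subjects: int = 500
    n_taxa: int = 50
    n_planted_binary: int = 2
    n_planted_continuous: int = 1
    effect_sizes: tuple[float, ...] = (0.8, -0.8, 1.5)
    noise_sd: float = 0.3
    base_concentration: tuple[float, ...] | None = None
    library_size_range: tuple[int, int] = (2000, 10000)
    strata_fractions: tuple[float, float, float] = (0.84, 0.11, 0.05)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be a positive integer")
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be a positive integer")
        if self.n_planted_binary < 0 or self.n_planted_continuous < 0:
            raise ValueError("n_planted_binary/n_planted_continuous must be >= 0")
        n_planted = self.n_planted_binary + self.n_planted_continuous
        if n_planted > self.n_taxa:
            raise ValueError("n_planted_binary + n_planted_continuous cannot exceed n_taxa")
        if len(self.effect_sizes) != n_planted:
            raise ValueError(
                f"effect_sizes must have one entry per planted taxon "
                f"({n_planted}), got {len(self.effect_sizes)}"
            )
        if any(e == 0 for e in self.effect_sizes):
            raise ValueError("effect_sizes entries must be nonzero")
        if not (self.noise_sd > 0):
            raise ValueError("noise_sd must be a positive real")
        lo, hi = self.library_size_range
        if lo < 100 or hi < lo:
            raise ValueError("library_size_range must satisfy 100 <= min <= max")
        if abs(sum(self.strata_fractions) - 1.0) > 1e-9:
            raise ValueError("strata_fractions must sum to 1 within 1e-9")
        if any(f < 0 for f in self.strata_fractions):
            raise ValueError("strata_fractions must be nonnegative")
        if self.base_concentration is not None:
            if len(self.base_concentration) != self.n_taxa:
                raise ValueError("base_concentration must have length n_taxa")
            if any(c <= 0 for c in self.base_concentration):
                raise ValueError("base_concentration entries must be positive")

    @classmethod
    def from_dict(cls, raw: dict) -> "SyntheticSpec":
        kwargs = dict(raw)
        for key in ("effect_sizes", "base_concentration", "library_size_range", "strata_fractions"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def concentration(self) -> np.ndarray:
        if self.base_concentration is not None:
            return np.asarray(self.base_concentration, dtype=float)
        return _default_concentration(self.n_taxa)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of the planted taxon effects."""

    planted_ids: tuple[str, ...]
    mechanisms: tuple[str, ...]  # "binary" | "continuous"
    true_signs: tuple[str, ...]  # "+" | "-"
    true_coefficients: tuple[float, ...]

    def __post_init__(self) -> None:
        k = len(self.planted_ids)
        if not (len(self.mechanisms) == len(self.true_signs) == len(self.true_coefficients) == k):
            raise ValueError("truth fields must have one entry per planted taxon")
        for sign, coef in zip(self.true_signs, self.true_coefficients):
            if sign not in ("+", "-") or (sign == "+") != (coef > 0):
                raise ValueError("true_signs must be consistent with true_coefficients")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        raw = json.loads(text)
        return cls(**{k: tuple(v) for k, v in raw.items()})


@dataclass
class Cohort:
    clinical: pd.DataFrame
    table: FeatureTable
    scores: pd.DataFrame
    truth: SyntheticTruth


def _taxon_catalog(n_taxa: int) -> tuple[list[str], list[str]]:
    ids, lineages = [], []
    for i in range(n_taxa):
        phylum, cls, order, family, genus = _GENUS_POOL[i % len(_GENUS_POOL)]
        suffix = "" if i < len(_GENUS_POOL) else f"_{i // len(_GENUS_POOL) + 1}"
        ids.append(f"g__{genus}{suffix}")
        lineages.append(
            f"k__Bacteria; p__{phylum}; c__{cls}; o__{order}; f__{family}; g__{genus}{suffix}; s__"
        )
    return ids, lineages


def _draw_clinical(rng: np.random.Generator, labels: np.ndarray, model: RiskModel) -> pd.DataFrame:
    """Stratum-conditional covariates, rejection-resampled onto their stratum.

    Each subject is redrawn (up to 50 rounds) until the computed risk score
    falls in the labelled stratum; stubborn subjects keep their last draw.
    """
    n = len(labels)
    df = pd.DataFrame(index=range(n), columns=CLINICAL_COLUMNS)
    df["subject_id"] = [f"S{i:05d}" for i in range(n)]
    pending = np.ones(n, dtype=bool)
    for _ in range(50):
        idx = np.flatnonzero(pending)
        if idx.size == 0:
            break
        for g in GROUPS:
            gi = idx[labels[idx] == g]
            if gi.size == 0:
                continue
            p = _STRATUM_PARAMS[g]
            df.loc[gi, "sex"] = np.where(rng.random(gi.size) < 0.5, "male", "female")
            df.loc[gi, "age"] = np.clip(rng.normal(*p["age"], gi.size), 20.0, 85.0)
            df.loc[gi, "total_chol"] = np.clip(rng.normal(*p["chol"], gi.size), 2.5, 10.0)
            df.loc[gi, "hdl"] = np.clip(rng.normal(*p["hdl"], gi.size), 0.6, 3.0)
            df.loc[gi, "sbp"] = np.clip(rng.normal(*p["sbp"], gi.size), 90.0, 200.0)
            df.loc[gi, "bp_treated"] = rng.random(gi.size) < p["bp_treated"]
            df.loc[gi, "smoker"] = rng.random(gi.size) < p["smoker"]
            df.loc[gi, "diabetic"] = rng.random(gi.size) < p["diabetic"]
        sub = df.loc[idx].copy()
        for col in ("age", "total_chol", "hdl", "sbp"):
            sub[col] = sub[col].astype(float)
        for col in ("bp_treated", "smoker", "diabetic"):
            sub[col] = sub[col].astype(bool)
        scores = score_frame(sub, model)
        ok = np.array([stratify(s) == g for s, g in zip(scores, labels[idx])])
        pending[idx[ok]] = False
    for col in ("age", "total_chol", "hdl", "sbp"):
        df[col] = df[col].astype(float)
    for col in ("bp_treated", "smoker", "diabetic"):
        df[col] = df[col].astype(bool)
    df["sex"] = df["sex"].astype(str)
    return df


def generate_cohort(spec: SyntheticSpec, model: RiskModel | None = None) -> Cohort:
    """Generate clinical covariates, counts, outcome scores and ground truth."""
    model = model or default_risk_model()
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_subjects, spec.n_taxa
    n_planted = spec.n_planted_binary + spec.n_planted_continuous

    # --- clinical covariates targeting the strata mix
    labels = rng.choice(len(GROUPS), size=n, p=np.asarray(spec.strata_fractions))
    labels = np.asarray(GROUPS)[labels]
    clinical = _draw_clinical(rng, labels, model)
    base_score = score_frame(clinical, model)
    base_log = np.log(np.maximum(base_score, 1e-6))

    # --- planted taxa: moderately abundant so presence is informative
    taxon_ids, lineages = _taxon_catalog(p)
    start = min(5, p - n_planted)
    planted_idx = np.arange(start, start + n_planted)
    mechanisms = ["binary"] * spec.n_planted_binary + ["continuous"] * spec.n_planted_continuous
    effects = np.asarray(spec.effect_sizes, dtype=float)

    # --- composition and counts (Dirichlet-multinomial)
    conc = spec.concentration()
    comp = rng.dirichlet(conc, size=n)  # subjects x taxa
    center = np.median(base_log)
    for k, (j, mech) in enumerate(zip(planted_idx, mechanisms)):
        if mech == "continuous":
            # overdispersed marginal: same mean proportion, 1/10 precision
            a = conc[j] * _CONTINUOUS_DISPERSION
            b = (conc.sum() - conc[j]) * _CONTINUOUS_DISPERSION
            p_j = rng.beta(a, b, size=n)
            comp[:, j] = 0.0
            comp *= ((1.0 - p_j) / comp.sum(axis=1))[:, None]
            comp[:, j] = p_j
        else:  # binary: presence tracks the baseline log score
            prob = expit(np.sign(effects[k]) * _PRESENCE_SLOPE * (base_log - center))
            absent = rng.random(n) >= prob
            comp[absent, j] = 0.0
    comp /= comp.sum(axis=1, keepdims=True)
    lib = rng.integers(spec.library_size_range[0], spec.library_size_range[1] + 1, size=n)
    counts = np.empty((n, p), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(lib[i], comp[i])

    # --- outcome: baseline + planted effects + noise, on the log-score scale
    rel = counts / lib[:, None]
    log_score = base_log.copy()
    for k, (j, mech) in enumerate(zip(planted_idx, mechanisms)):
        if mech == "binary":
            log_score += effects[k] * (counts[:, j] > 0)
        else:
            log_score += effects[k] * np.arcsin(np.sqrt(rel[:, j]))
    log_score += rng.normal(0.0, spec.noise_sd, size=n)
    score = np.clip(np.exp(log_score), 1e-6, 100.0)

    scores = pd.DataFrame(
        {
            "subject_id": clinical["subject_id"],
            "baseline_score": base_score,
            "score": score,
            "log_score": np.log(score),
            "group": [stratify(s) for s in score],
        }
    )
    table = FeatureTable(
        counts=counts.T, taxon_ids=taxon_ids, sample_ids=clinical["subject_id"].tolist(),
        lineages=lineages,
    )
    truth = SyntheticTruth(
        planted_ids=tuple(taxon_ids[j] for j in planted_idx),
        mechanisms=tuple(mechanisms),
        true_signs=tuple("+" if e > 0 else "-" for e in effects),
        true_coefficients=tuple(float(e) for e in effects),
    )
    return Cohort(clinical=clinical, table=table, scores=scores, truth=truth)


def write_cohort(cohort: Cohort, directory) -> dict[str, Path]:
    """Write feature-table TSV, clinical CSV, scores CSV and truth JSON."""
    if len(cohort.clinical) == 0 or cohort.table.n_samples == 0:
        raise ValueError("refusing to write an empty cohort")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "feature_table": directory / "feature_table.tsv",
        "clinical": directory / "clinical.csv",
        "scores": directory / "scores.csv",
        "truth": directory / "truth.json",
    }
    write_feature_table(cohort.table, paths["feature_table"])
    cohort.clinical.to_csv(paths["clinical"], index=False)
    cohort.scores.to_csv(paths["scores"], index=False)
    paths["truth"].write_text(cohort.truth.to_json())
    return paths


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("bp_treated", "smoker", "diabetic"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df
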