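"""End-to-end orchestration: score -> stratify -> collapse -> transform ->
stability-select -> diversity, with every table and a machine-readable
summary written to a run directory.

A run is configured by a YAML mapping (see :class:`RunConfig`). Input is
either a feature-table TSV plus clinical CSV, or a ``simulate`` block of
:class:`~smcvd.synthetic_cohort.SyntheticSpec` fields for a fully synthetic
run. Reruns with the same config and seed reproduce all value-level outputs;
the summary JSON contains no timestamps so it is byte-identical across
reruns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diversity_stats import ALPHA_INDICES, alpha_diversity, anosim, bray_curtis, mann_whitney
from .feature_io import RANKS, collapse_taxonomy, read_feature_table, relative_abundance, write_feature_table
from .penalized_models import PENALTIES
from .risk_score import default_risk_model, load_risk_model, score_cohort
from .stability_selection import (
    SplitPlan,
    compare_mse,
    pertinent_features,
    run_stability,
    sign_summary,
    write_pertinent_json,
)
from .synthetic_cohort import SyntheticSpec, generate_cohort, read_clinical, write_cohort
from .transforms import arcsin_transform, binary_transform, log_outcome

__all__ = ["RunConfig", "run_pipeline", "demo_config"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    outdir: Path
    feature_table: Path | None = None
    clinical: Path | None = None
    risk_model: Path | None = None
    simulate: SyntheticSpec | None = None
    rank: str = "genus"
    transforms: tuple[str, ...] = ("binary", "arcsin")
    methods: tuple[str, ...] = PENALTIES
    n_splits: int = 50
    train_fraction: float = 0.8
    cv_folds: int = 10
    threshold: float = 0.8
    pertinent_mode: str = "all"
    anosim_permutations: int = 999
    alpha_indices: tuple[str, ...] = ALPHA_INDICES
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.simulate is None and (self.feature_table is None or self.clinical is None):
            raise ValueError("config needs either a 'simulate' block or feature_table + clinical paths")
        for name in ("feature_table", "clinical", "risk_model"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise ValueError(f"{name} file does not exist: {path}")
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError(f"threshold must be in (0, 1], got {self.threshold}")
        unknown = set(self.methods) - set(PENALTIES)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        unknown_t = set(self.transforms) - {"binary", "arcsin"}
        if unknown_t:
            raise ValueError(f"unknown transforms: {sorted(unknown_t)}")
        bad_idx = set(self.alpha_indices) - set(ALPHA_INDICES)
        if bad_idx:
            raise ValueError(f"unknown alpha indices: {sorted(bad_idx)}")

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path | None = None) -> "RunConfig":
        raw = dict(raw)
        base = Path(base_dir) if base_dir else Path.cwd()

        def _path(key):
            v = raw.pop(key, None)
            if v is None:
                return None
            p = Path(v)
            return p if p.is_absolute() else base / p

        sim = raw.pop("simulate", None)
        kwargs = dict(
            outdir=Path(raw.pop("outdir", "smcvd_run")),
            feature_table=_path("feature_table"),
            clinical=_path("clinical"),
            risk_model=_path("risk_model"),
            simulate=SyntheticSpec.from_dict(sim) if sim else None,
        )
        for key in (
            "rank", "n_splits", "train_fraction", "cv_folds", "threshold",
            "pertinent_mode", "anosim_permutations", "master_seed",
        ):
            if key in raw:
                kwargs[key] = raw.pop(key)
        for key in ("transforms", "methods", "alpha_indices"):
            if key in raw:
                kwargs[key] = tuple(raw.pop(key))
        if raw:
            raise ValueError(f"unknown config keys: {sorted(raw)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh), base_dir=path.parent)


def demo_config(outdir) -> RunConfig:
    """The bundled synthetic demo: 3 planted binary-mechanism taxa, small run."""
    ref = resources.files("smcvd.data").joinpath("demo_config.yaml")
    raw = yaml.safe_load(ref.read_text())
    raw["outdir"] = str(outdir)
    return RunConfig.from_dict(raw)


def _group_pvalues(alpha: pd.Series, groups: pd.Series) -> dict:
    """Pairwise Mann-Whitney p-values of an alpha index between risk groups."""
    out = {}
    present = [g for g in ("LR", "MR", "HR") if (groups == g).sum() >= 2]
    for i, ga in enumerate(present):
        for gb in present[i + 1 :]:
            _, p = mann_whitney(alpha[groups == ga].to_numpy(), alpha[groups == gb].to_numpy())
            out[f"{ga}_vs_{gb}"] = p
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    On any stage failure a ``FAILED`` marker file is written next to the
    partial outputs and the exception re-raised.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("smcvd")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        result = _run_stages(config, outdir)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
    return result


def _run_stages(config: RunConfig, outdir: Path) -> Path:
    model = load_risk_model(config.risk_model) if config.risk_model else default_risk_model()
    logger.info("smcvd %s, master_seed=%d", __version__, config.master_seed)

    truth = None
    if config.simulate is not None:
        logger.info("simulating cohort: %s", config.simulate)
        cohort = generate_cohort(config.simulate, model)
        write_cohort(cohort, outdir / "cohort")
        clinical, table = cohort.clinical, cohort.table
        scores = cohort.scores[["subject_id", "score", "group"]].copy()
        truth = cohort.truth
    else:
        clinical = read_clinical(config.clinical)
        table = read_feature_table(config.feature_table)
        scores = score_cohort(clinical, model)

    # risk scoring / stratification
    scores.to_csv(outdir / "risk_scores.csv", index=False)
    group_counts = scores["group"].value_counts().to_dict()
    logger.info("risk group counts: %s", group_counts)

    # taxonomy collapse and transforms
    collapsed = collapse_taxonomy(table, config.rank)
    write_feature_table(collapsed, outdir / f"table_{config.rank}.tsv")
    sample_order = {s: i for i, s in enumerate(collapsed.sample_ids)}
    scores = scores.sort_values("subject_id", key=lambda s: s.map(sample_order)).reset_index(drop=True)
    if list(scores["subject_id"]) != list(collapsed.sample_ids):
        raise ValueError("sample ids of the feature table and clinical table do not match")
    y = log_outcome(scores["score"].to_numpy())

    designs = {}
    if "binary" in config.transforms:
        designs["binary"] = binary_transform(collapsed)
    if "arcsin" in config.transforms:
        designs["arcsin"] = arcsin_transform(relative_abundance(collapsed, rank=config.rank))

    # stability selection
    plan = SplitPlan(
        n_splits=config.n_splits,
        train_fraction=config.train_fraction,
        master_seed=config.master_seed,
    )
    report = run_stability(designs, y, plan, methods=config.methods, cv_folds=config.cv_folds)
    report.write_tables(outdir)
    pertinent = pertinent_features(report, threshold=config.threshold, mode=config.pertinent_mode)
    write_pertinent_json(pertinent, outdir / "pertinent_sets.json")
    signs = sign_summary(report)
    signs.to_csv(outdir / "sign_summary.tsv", sep="\t", index=False)
    mse_cmp = compare_mse(report)
    mse_cmp["summary"].to_csv(outdir / "mse_summary.tsv", sep="\t", index=False)

    # direction calls for the common markers (pooled over methods/transforms)
    direction_calls = {}
    for fid in sorted(pertinent["common"]):
        sub = signs[signs["feature"] == fid]
        npos, nneg = int(sub["n_positive"].sum()), int(sub["n_negative"].sum())
        direction_calls[fid] = (
            "risk-increasing" if npos > nneg else "risk-decreasing" if nneg > npos else "mixed"
        )

    # diversity
    groups = scores.set_index("subject_id").loc[collapsed.sample_ids, "group"]
    alpha_frames = {}
    alpha_pvalues = {}
    for index in config.alpha_indices:
        a = alpha_diversity(collapsed, index)
        alpha_frames[index] = a
        alpha_pvalues[index] = _group_pvalues(a, groups)
    pd.DataFrame(alpha_frames).to_csv(outdir / "alpha_diversity.tsv", sep="\t", index_label="sample")
    dm = bray_curtis(collapsed)
    dm.write_tsv(outdir / "bray_curtis.tsv")
    if groups.nunique() >= 2 and groups.value_counts().min() >= 2:
        r_stat, anosim_p = anosim(
            dm, groups.to_numpy(), n_perm=config.anosim_permutations, seed=config.master_seed
        )
    else:
        logger.warning("fewer than 2 groups with >= 2 members; ANOSIM skipped")
        r_stat, anosim_p = float("nan"), float("nan")

    summary = {
        "version": __version__,
        "master_seed": config.master_seed,
        "n_subjects": int(len(scores)),
        "n_features": int(collapsed.n_taxa),
        "rank": config.rank,
        "group_counts": {g: int(group_counts.get(g, 0)) for g in ("LR", "MR", "HR")},
        "pertinent": {
            "per_transform": {k: sorted(v) for k, v in pertinent["per_transform"].items()},
            "common": sorted(pertinent["common"]),
            "specific": {k: sorted(v) for k, v in pertinent["specific"].items()},
        },
        "direction_calls": direction_calls,
        "mse_medians": {
            f"{row.method}/{row.transform}": row.median
            for row in mse_cmp["summary"].itertuples()
        },
        "alpha_pvalues": alpha_pvalues,
        "anosim": {"R": r_stat, "p": anosim_p},
        "split_plan": {
            "n_splits": config.n_splits,
            "train_fraction": config.train_fraction,
            "cv_folds": config.cv_folds,
            "threshold": config.threshold,
            "pertinent_mode": config.pertinent_mode,
        },
    }
    if truth is not None:
        summary["synthetic_truth"] = {
            "planted_ids": list(truth.planted_ids),
            "mechanisms": list(truth.mechanisms),
            "true_signs": list(truth.true_signs),
        }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    logger.info("run complete: %s", outdir)
    return outdir
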