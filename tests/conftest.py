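import numpy as np
import pytest

from smcvd.feature_io import FeatureTable, relative_abundance
from smcvd.risk_score import RiskModel, RiskTerm, SexModel
from smcvd.stability_selection import SplitPlan, run_stability
from smcvd.synthetic_cohort import SyntheticSpec, generate_cohort
from smcvd.transforms import arcsin_transform, binary_transform, log_outcome


@pytest.fixture(scope="session")
def toy_table() -> FeatureTable:
    """3 taxa x 4 samples with two OTUs sharing a genus."""
    counts = np.array(
        [
            [3, 0, 5, 2],
            [4, 1, 0, 0],
            [2, 7, 1, 9],
        ]
    )
    lineages = [
        "k__Bacteria; p__Firmicutes; c__Bacilli; o__Lactobacillales; f__Streptococcaceae; g__Streptococcus; s__",
        "k__Bacteria; p__Firmicutes; c__Bacilli; o__Lactobacillales; f__Streptococcaceae; g__Streptococcus; s__mitis",
        "k__Bacteria; p__Bacteroidetes; c__Bacteroidia; o__Bacteroidales; f__Prevotellaceae; g__Prevotella; s__",
    ]
    return FeatureTable(
        counts=counts,
        taxon_ids=["otu1", "otu2", "otu3"],
        sample_ids=["s1", "s2", "s3", "s4"],
        lineages=lineages,
    )


@pytest.fixture(scope="session")
def toy_risk_model() -> RiskModel:
    """Single-term toy model: s0=0.95, beta=0.5, xbar=2, identity link."""
    term = RiskTerm(name="age_lin", factor="age", beta=0.5, mean=2.0, log=False)
    return RiskModel(sexes={"male": SexModel(s0=0.95, terms=(term,)), "female": SexModel(s0=0.95, terms=(term,))})


@pytest.fixture(scope="session")
def small_cohort():
    """Shared mid-size synthetic cohort (2 binary + 1 continuous planted taxa)."""
    return generate_cohort(SyntheticSpec(n_subjects=400, n_taxa=30, seed=5))


@pytest.fixture(scope="session")
def small_report(small_cohort):
    """Stability report on the shared cohort (15 splits, all methods)."""
    c = small_cohort
    y = log_outcome(c.scores["score"].to_numpy())
    designs = {
        "binary": binary_transform(c.table),
        "arcsin": arcsin_transform(relative_abundance(c.table)),
    }
    plan = SplitPlan(n_splits=15, master_seed=11)
    return run_stability(designs, y, plan)
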