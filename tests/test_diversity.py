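import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu, rankdata

from smcvd.diversity_stats import (
    DistanceMatrix,
    alpha_diversity,
    anosim,
    bray_curtis,
    mann_whitney,
)
from smcvd.feature_io import FeatureTable


def _table(counts):
    counts = np.asarray(counts)
    return FeatureTable(
        counts=counts,
        taxon_ids=[f"t{i}" for i in range(counts.shape[0])],
        sample_ids=[f"s{j}" for j in range(counts.shape[1])],
        lineages=["k__B"] * counts.shape[0],
    )


class TestAlpha:
    def test_uniform_closed_forms(self):
        table = _table(np.full((4, 1), 10))
        assert alpha_diversity(table, "shannon").iloc[0] == pytest.approx(math.log(4), abs=1e-9)
        assert alpha_diversity(table, "simpson").iloc[0] == pytest.approx(0.75, abs=1e-9)
        assert alpha_diversity(table, "observed").iloc[0] == 4

    def test_single_taxon_zero_diversity(self):
        table = _table([[42]])
        assert alpha_diversity(table, "shannon").iloc[0] == 0.0
        assert alpha_diversity(table, "simpson").iloc[0] == 0.0

    def test_chao1_bias_corrected_arithmetic(self):
        # S_obs=10, F1=4, F2=2 -> 10 + 4*3/(2*3) = 12
        counts = np.array([1, 1, 1, 1, 2, 2, 3, 5, 7, 9])[:, None]
        table = _table(counts)
        assert alpha_diversity(table, "chao1").iloc[0] == pytest.approx(12.0, abs=1e-9)

    def test_chao1_classical_form(self):
        counts = np.array([1, 1, 1, 1, 2, 2, 3, 5, 7, 9])[:, None]
        table = _table(counts)
        got = alpha_diversity(table, "chao1", chao1_bias_corrected=False).iloc[0]
        assert got == pytest.approx(10 + 16 / 4, abs=1e-9)

    def test_empty_sample_zero_with_warning(self, caplog):
        import logging

        table = _table([[0], [0]])
        with caplog.at_level(logging.WARNING):
            vals = alpha_diversity(table, "chao1")
        assert vals.iloc[0] == 0.0
        assert "empty" in caplog.text

    @given(
        st.lists(st.integers(min_value=1, max_value=500), min_size=3, max_size=8)
    )
    @settings(max_examples=100, derandomize=True)
    def test_shannon_maximised_by_uniform(self, counts):
        k = len(counts)
        observed = alpha_diversity(_table(np.array(counts)[:, None]), "shannon").iloc[0]
        assert observed <= math.log(k) + 1e-12


class TestBrayCurtis:
    def test_hand_examples(self):
        table = _table([[1, 2], [2, 1]])
        dm = bray_curtis(table)
        assert dm.values[0, 1] == pytest.approx(1 / 3, abs=1e-12)

    def test_identical_samples_zero(self):
        dm = bray_curtis(_table([[3, 3], [7, 7]]))
        assert dm.values[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        dm = bray_curtis(_table([[5, 0], [0, 9]]))
        assert dm.values[0, 1] == 1.0

    def test_metric_axioms_except_triangle(self):
        rng = np.random.default_rng(0)
        dm = bray_curtis(_table(rng.integers(0, 30, size=(12, 8))))
        v = dm.values
        assert np.allclose(v, v.T, atol=1e-12)
        assert np.all(np.diag(v) == 0)
        assert v.min() >= 0 and v.max() <= 1

    def test_two_all_zero_samples_distance_zero(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            dm = bray_curtis(_table([[0, 0, 1], [0, 0, 2]]))
        assert dm.values[0, 1] == 0.0
        assert "all-zero" in caplog.text


def _brute_force_anosim(values, groups):
    """Independent enumeration oracle: R for every distinct 2-group labelling."""
    n = len(groups)
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(values[iu])
    labels = sorted(set(groups))
    k = sum(1 for g in groups if g == labels[0])

    def r_for(assignment):
        g = np.asarray(assignment)
        within = g[iu[0]] == g[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / (n * (n - 1) / 4.0)

    r_obs = r_for(groups)
    rs = []
    for combo in itertools.combinations(range(n), k):
        g = np.array([labels[0] if i in combo else labels[1] for i in range(n)])
        rs.append(r_for(g))
    rs = np.asarray(rs)
    return r_obs, float((rs >= r_obs - 1e-12).mean())


class TestAnosim:
    def _separated(self):
        # two tight clusters far apart: all between > all within
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.1, size=(4, 3))
        b = rng.normal(10, 0.1, size=(4, 3))
        pts = np.vstack([a, b])
        n = len(pts)
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        np.fill_diagonal(D, 0.0)
        dm = DistanceMatrix(labels=[f"s{i}" for i in range(n)], values=D)
        groups = np.array(["x"] * 4 + ["y"] * 4)
        return dm, groups

    def test_perfect_separation_r_one(self):
        dm, groups = self._separated()
        r, _ = anosim(dm, groups, n_perm=99, seed=0)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_exhaustive_matches_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(8, 3))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        np.fill_diagonal(D, 0.0)
        dm = DistanceMatrix(labels=[f"s{i}" for i in range(8)], values=D)
        groups = np.array(["x"] * 4 + ["y"] * 4)
        r, p = anosim(dm, groups, exhaustive=True)
        r_ref, p_ref = _brute_force_anosim(D, groups)
        assert r == pytest.approx(r_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-12)

    def test_sampled_agrees_with_exhaustive_within_mc_error(self):
        rng = np.random.default_rng(3)
        pts = np.vstack([rng.normal(0, 1, (4, 2)), rng.normal(1.0, 1, (4, 2))])
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        np.fill_diagonal(D, 0.0)
        dm = DistanceMatrix(labels=[f"s{i}" for i in range(8)], values=D)
        groups = np.array(["x"] * 4 + ["y"] * 4)
        _, p_ex = anosim(dm, groups, exhaustive=True)
        _, p_mc = anosim(dm, groups, n_perm=1999, seed=0)
        mc_sd = math.sqrt(p_ex * (1 - p_ex) / 1999)
        assert abs(p_mc - p_ex) < 4 * mc_sd + 1e-3

    def test_exchangeable_labels_null_r_near_zero(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(16, 4))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        np.fill_diagonal(D, 0.0)
        dm = DistanceMatrix(labels=[f"s{i}" for i in range(16)], values=D)
        groups = np.array(["x"] * 8 + ["y"] * 8)
        r, p = anosim(dm, groups, n_perm=999, seed=1)
        assert abs(r) < 0.3
        assert p > 0.05

    def test_matches_scikit_bio(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.stats.distance import anosim as skbio_anosim

        rng = np.random.default_rng(6)
        pts = np.vstack([rng.normal(0, 1, (5, 3)), rng.normal(2, 1, (5, 3))])
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        np.fill_diagonal(D, 0.0)
        labels = [f"s{i}" for i in range(10)]
        groups = ["x"] * 5 + ["y"] * 5
        r, _ = anosim(DistanceMatrix(labels=labels, values=D), np.array(groups), n_perm=99, seed=0)
        ref = skbio_anosim(SkbioDM(D, ids=labels), grouping=groups, permutations=0)
        assert r == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_singleton_group_rejected(self):
        dm = DistanceMatrix(labels=["a", "b", "c"], values=1 - np.eye(3))
        with pytest.raises(ValueError, match="2 members"):
            anosim(dm, np.array(["x", "x", "y"]))


class TestMannWhitney:
    def test_extreme_separation_exact(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)  # 2/20 assignments as extreme

    def test_identical_multisets_u_half(self):
        x = [1.0, 2.0, 5.0, 9.0]
        u, _ = mann_whitney(x, x)
        assert u == len(x) * len(x) / 2

    def test_all_identical_values_p_one(self):
        _, p = mann_whitney([3.0, 3.0], [3.0, 3.0, 3.0])
        assert p == 1.0

    def test_large_shift_significant(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 50)
        y = rng.normal(2, 1, 50)
        _, p = mann_whitney(x, y)
        assert p < 0.001

    def test_exact_region_matches_scipy(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=5)
        y = rng.normal(size=6)
        u, p = mann_whitney(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert u == ref.statistic
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_approx_region_close_to_scipy(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.5, 1, 35)
        u, p = mann_whitney(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert u == ref.statistic
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestDistanceMatrix:
    def test_asymmetry_rejected(self):
        v = np.array([[0.0, 0.5], [0.4, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(labels=["a", "b"], values=v)

    def test_nonzero_diagonal_rejected(self):
        v = np.array([[0.1, 0.5], [0.5, 0.0]])
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(labels=["a", "b"], values=v)
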