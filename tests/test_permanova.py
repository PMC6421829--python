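"""Gower centering, pseudo-F, permutation p-values and rarefied pooling."""

import numpy as np
import pytest
from itertools import permutations

from scipy.spatial.distance import pdist, squareform
from scipy.stats import linregress

from benthodiv import gower_center, permanova_rarefied, permanova_single, pseudo_f
from benthodiv.alpha import rarefy_counts
from benthodiv._utils import derive_rng


def euclid(points: np.ndarray) -> np.ndarray:
    return squareform(pdist(np.atleast_2d(points.T).T if points.ndim == 1 else points))


class TestGowerCenter:
    def test_zero_matrix_stays_zero(self):
        G = gower_center(np.zeros((4, 4)))
        assert np.allclose(G, 0)

    def test_huygens_identity_on_a_line(self):
        # trace of G equals the centroid sum of squares of the generating points
        pts = np.array([0.0, 3.0, 4.0])
        G = gower_center(np.abs(pts[:, None] - pts[None, :]))
        assert np.trace(G) == pytest.approx(np.sum((pts - pts.mean()) ** 2))
        assert np.trace(G) == pytest.approx(26 / 3)

    def test_double_centering_kills_row_sums(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(6, 3))
        G = gower_center(euclid(pts))
        assert np.allclose(G.sum(axis=0), 0, atol=1e-10)
        assert np.allclose(G.sum(axis=1), 0, atol=1e-10)


class TestPseudoF:
    def test_equals_classical_anova_on_worked_example(self):
        y = np.array([1.0, 2, 3, 10, 11, 12])
        D = np.abs(y[:, None] - y[None, :])
        F, R2 = pseudo_f(gower_center(D), np.array(["a", "a", "a", "b", "b", "b"]))
        # hand ANOVA: SSB = 121.5, SSW = 4, df = (1, 4)
        assert F == pytest.approx(121.5, abs=1e-9)
        assert R2 == pytest.approx(121.5 / 125.5, abs=1e-12)

    def test_numeric_covariate_matches_univariate_regression(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=9)
        x = rng.normal(size=9)
        F, R2 = pseudo_f(gower_center(np.abs(y[:, None] - y[None, :])), x)
        reg = linregress(x, y)
        assert R2 == pytest.approx(reg.rvalue ** 2, abs=1e-10)
        n = len(y)
        F_reg = reg.rvalue ** 2 / (1 - reg.rvalue ** 2) * (n - 2)
        assert F == pytest.approx(F_reg, abs=1e-8)

    def test_orthogonal_covariate_has_no_signal(self):
        coords = np.array([1.0, 1, -1, -1])
        x = np.array([1.0, -1, 1, -1])  # orthogonal to coords and to 1
        F, R2 = pseudo_f(gower_center(np.abs(coords[:, None] - coords[None, :])), x)
        assert F == pytest.approx(0.0, abs=1e-10)
        assert R2 == pytest.approx(0.0, abs=1e-12)

    def test_constant_covariate_is_error(self):
        D = euclid(np.random.default_rng(0).normal(size=(5, 2)))
        with pytest.raises(ValueError, match="constant"):
            pseudo_f(gower_center(D), np.ones(5))

    def test_degenerate_distances_give_zero_f(self):
        F, R2 = pseudo_f(np.zeros((5, 5)), np.arange(5.0))
        assert F == 0.0 and R2 == 0.0

    def test_matches_direct_sums_of_squares_on_random_data(self):
        # multivariate oracle computed from raw coordinates, never distances
        rng = np.random.default_rng(42)
        for _ in range(50):
            n, d = rng.integers(6, 12), rng.integers(1, 4)
            Y = rng.normal(size=(n, d))
            g = rng.integers(0, 2, size=n)
            if g.min() == g.max():
                g[0] = 1 - g[0]
            grand = Y.mean(axis=0)
            ssb = sum((g == k).sum() * np.sum((Y[g == k].mean(axis=0) - grand) ** 2)
                      for k in (0, 1))
            ssw = sum(np.sum((Y[g == k] - Y[g == k].mean(axis=0)) ** 2) for k in (0, 1))
            F_direct = (ssb / 1) / (ssw / (n - 2))
            F, R2 = pseudo_f(gower_center(euclid(Y)), g.astype(str))
            assert F == pytest.approx(F_direct, rel=1e-9)
            assert R2 == pytest.approx(ssb / (ssb + ssw), rel=1e-9)


class TestPermutationP:
    def test_exhaustive_matches_regression_enumeration_oracle(self):
        # independent oracle: classical regression F recomputed from the raw
        # 1-D coordinates for every one of the 4! relabelings
        y = np.array([0.0, 1.0, 3.5, 7.0])
        x = np.array([2.0, 1.0, 5.0, 3.0])
        D = np.abs(y[:, None] - y[None, :])
        res = permanova_single(D, x, exhaustive=True)
        fs = []
        for perm in permutations(range(4)):
            r = linregress(x[list(perm)], y).rvalue
            fs.append(r * r / (1 - r * r) * 2)
        fs = np.array(fs)
        expected = (fs >= res.F - res.epsilon).mean()
        assert res.p == pytest.approx(expected, abs=1e-15)

    def test_joint_relabeling_leaves_p_unchanged(self):
        y = np.array([0.0, 1.0, 3.5, 7.0])
        x = np.array([2.0, 1.0, 5.0, 3.0])
        D = np.abs(y[:, None] - y[None, :])
        order = [2, 0, 3, 1]
        res1 = permanova_single(D, x, exhaustive=True)
        res2 = permanova_single(D[np.ix_(order, order)], x[order], exhaustive=True)
        assert res1.p == pytest.approx(res2.p, abs=1e-15)
        assert res1.F == pytest.approx(res2.F, rel=1e-12)

    def test_perfect_separation_attains_smallest_p(self):
        # monotone covariate on perfectly ordered points: only the identity
        # and full reversal tie the observed F, and neither is drawn here
        y = np.arange(8.0)
        D = np.abs(y[:, None] - y[None, :])
        res = permanova_single(D, y.copy(), n_perm=99, seed=4)
        assert res.p == pytest.approx(1 / 100)

    def test_p_is_never_zero(self):
        y = np.arange(6.0)
        D = np.abs(y[:, None] - y[None, :])
        for seed in range(5):
            res = permanova_single(D, y.copy(), n_perm=49, seed=seed)
            assert res.p >= 1 / 50

    def test_no_permutations_returns_nan_p(self):
        y = np.arange(5.0)
        D = np.abs(y[:, None] - y[None, :])
        res = permanova_single(D, y.copy(), n_perm=0)
        assert np.isnan(res.p) and res.F > 0


class TestRarefiedPooling:
    def test_single_rarefaction_reduces_to_permanova_single(self, small_dataset):
        dna = small_dataset.counts.split_fractions()["DNA"]
        x = small_dataset.env.aligned_to(dna.sample_ids).data["chlorophyll_sum"].to_numpy()
        seed = 13
        pooled = permanova_rarefied(dna, x, "bray_weighted", depth=9058,
                                    rarefactions=1, n_perm=99, seed=seed)
        rarefied = rarefy_counts(dna, 9058, rng=derive_rng(seed, "rarefy", 0))
        from benthodiv.beta import distance_matrix
        single = permanova_single(distance_matrix(rarefied, "bray_weighted"),
                                  x, n_perm=99, seed=seed)
        assert pooled.F == pytest.approx(single.F, rel=1e-12)
        assert pooled.R2 == pytest.approx(single.R2, rel=1e-12)
        assert pooled.p == pytest.approx(single.p, abs=1e-15)

    def test_trace_has_one_row_per_rarefaction(self, small_dataset):
        dna = small_dataset.counts.split_fractions()["DNA"]
        x = small_dataset.env.aligned_to(dna.sample_ids).data["chlorophyll_sum"].to_numpy()
        res = permanova_rarefied(dna, x, "bray_weighted", depth=9058,
                                 rarefactions=5, n_perm=19, seed=1)
        assert len(res.trace) == 5
        assert res.n_rarefactions == 5 and res.n_perm == 19
        assert 0 < res.p <= 1

    def test_shared_permutation_mode_runs(self, small_dataset):
        dna = small_dataset.counts.split_fractions()["DNA"]
        x = small_dataset.env.aligned_to(dna.sample_ids).data["chlorophyll_sum"].to_numpy()
        res = permanova_rarefied(dna, x, "bray_weighted", depth=9058,
                                 rarefactions=3, n_perm=19, seed=1,
                                 permute_per_rarefaction=False)
        assert 0 < res.p <= 1


class TestCrossCheck:
    def test_categorical_f_matches_reference_implementation(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(7)
        Y = rng.normal(size=(12, 4))
        D = euclid(Y)
        groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        F, _ = pseudo_f(gower_center(D), np.array(groups))
        ref = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(D, ids=[str(i) for i in range(12)]),
            grouping=groups, permutations=0,
        )
        assert F == pytest.approx(ref["test statistic"], rel=1e-10)
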