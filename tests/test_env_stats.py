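"""Spearman machinery, depth filtering, chlorophyll integration, screens."""

import numpy as np
import pandas as pd
import pytest
from itertools import permutations

from scipy.stats import spearmanr

from benthodiv import (
    CountTable,
    EnvTable,
    alpha_env_screen,
    beta_env_screen,
    correlation_matrix,
    drop_low_depth,
    function_screen,
    integrate_chlorophyll,
    spearman_test,
)
from benthodiv.alpha import AlphaProfile
from benthodiv.tables import FunctionTable


class TestSpearman:
    def test_hand_value(self):
        # d^2 sums to 6: rho = 1 - 6*6/(3*8) = -0.5
        res = spearman_test([1, 2, 3], [3, 1, 2])
        assert res.rho == pytest.approx(-0.5)

    def test_monotone_transform_gives_unit_rho(self):
        x = np.array([0.3, 1.2, 5.0, 9.1, 12.0])
        res = spearman_test(x, np.exp(x))
        assert res.rho == pytest.approx(1.0)
        assert res.method == "exact"

    def test_exact_p_matches_enumeration_at_n4(self):
        x = np.array([1.0, 2, 3, 4])
        y = np.array([2.0, 1, 4, 3])
        res = spearman_test(x, y)
        rhos = np.array([spearmanr(x, y[list(p)]).statistic
                         for p in permutations(range(4))])
        expected = (np.abs(rhos) >= abs(res.rho) - 1e-12).mean()
        assert res.method == "exact"
        assert res.p == pytest.approx(expected, abs=1e-15)

    def test_exact_and_t_branches_agree_at_transect_n(self):
        # at n = 9 (the transect's station count) the two p-value routes
        # should differ by < 0.02 for moderate correlations
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 10:
            x = rng.normal(size=9)
            y = 0.4 * x + rng.normal(size=9)
            exact = spearman_test(x, y, method="exact")
            if abs(exact.rho) > 0.6:
                continue
            approx = spearman_test(x, y, method="approx")
            assert abs(exact.p - approx.p) < 0.02
            checked += 1

    def test_pairwise_complete_deletion(self):
        x = [1.0, 2, 3, np.nan, 5, 6, 7, 8]
        y = [2.0, 1, 4, 5, np.nan, 7, 6, 9]
        res = spearman_test(x, y)
        assert res.n == 6

    def test_zero_rank_variance_is_error(self):
        with pytest.raises(ValueError, match="variance"):
            spearman_test([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_few_pairs_is_error(self):
        with pytest.raises(ValueError, match="pairs"):
            spearman_test([1, 2], [2, 1])


class TestCorrelationMatrix:
    def test_duplicated_property_has_unit_rho(self):
        df = pd.DataFrame({"a": [1.0, 3, 2, 5, 4], "b": [1.0, 3, 2, 5, 4]},
                          index=list("vwxyz"))
        cm = correlation_matrix(EnvTable(df))
        assert cm.rho.loc["a", "b"] == pytest.approx(1.0)

    def test_symmetry(self, small_dataset):
        cm = correlation_matrix(small_dataset.station_env)
        assert np.allclose(cm.rho.values, cm.rho.values.T)
        assert np.allclose(cm.p.values, cm.p.values.T)
        assert np.allclose(np.diag(cm.rho.values), 1.0)

    def test_planted_copula_structure_recovered(self):
        from benthodiv.synthetic import SyntheticConfig, simulate_env
        env = simulate_env(SyntheticConfig(seed=3, n_stations=200))
        cm = correlation_matrix(env)
        assert cm.rho.loc["fe2o3", "water_depth"] == pytest.approx(0.8, abs=0.1)
        assert cm.rho.loc["latitude", "chlorophyll_sum"] == pytest.approx(0.8, abs=0.1)
        assert abs(cm.rho.loc["null_property", "chlorophyll_sum"]) < 0.2


class TestDropLowDepth:
    def test_zero_threshold_is_identity(self, tiny_table):
        out, report = drop_low_depth(tiny_table, 0)
        assert out.sample_ids == tiny_table.sample_ids
        assert report["n_removed"] == 0

    def test_removes_exactly_the_subthreshold_library(self):
        t = CountTable(np.array([[50, 0], [2500, 2500], [3000, 3000]]),
                       ["shallow", "mid", "deep"], ["a", "b"])
        out, report = drop_low_depth(t, 4941)
        assert out.sample_ids == ["mid", "deep"]
        assert report["removed"] == {"shallow": 50}

    def test_all_removed_is_error(self, tiny_table):
        with pytest.raises(ValueError, match="all"):
            drop_low_depth(tiny_table, 10_000)


class TestChlorophyllIntegration:
    def test_singleton(self):
        assert integrate_chlorophyll(pd.DataFrame(
            {"depth": [100.0], "concentration": [3.2]})) == pytest.approx(3.2)

    def test_cutoff_excludes_deep_readings(self):
        prof = pd.DataFrame({"depth": np.arange(100, 700, 100.0),
                             "concentration": np.ones(6)})
        assert integrate_chlorophyll(prof) == pytest.approx(5.0)  # 600 m excluded

    def test_empty_profile_is_error(self):
        with pytest.raises(ValueError):
            integrate_chlorophyll(pd.DataFrame({"depth": [], "concentration": []}))


def _profile_from(df: pd.DataFrame) -> AlphaProfile:
    return AlphaProfile(df, depth=100, iterations=1, seed=0)


class TestAlphaScreen:
    def test_shape_is_indices_by_properties_by_fractions(self, small_dataset):
        samples = [s for s in small_dataset.counts.sample_ids if s.endswith("dna")]
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"richness": rng.integers(400, 900, 9).astype(float),
                           "shannon": rng.uniform(5, 6, 9),
                           "faith_pd": rng.uniform(380, 520, 9),
                           "coverage": rng.uniform(80, 95, 9)}, index=samples)
        out = alpha_env_screen({"DNA": _profile_from(df)}, small_dataset.env)
        n_props = len(small_dataset.env.properties)
        assert len(out) == 4 * n_props

    def test_constant_index_becomes_na_row_with_note(self, small_dataset):
        samples = [s for s in small_dataset.counts.sample_ids if s.endswith("dna")]
        df = pd.DataFrame({"richness": np.full(9, 500.0),
                           "shannon": np.linspace(5, 6, 9),
                           "faith_pd": np.linspace(380, 520, 9),
                           "coverage": np.linspace(80, 95, 9)}, index=samples)
        out = alpha_env_screen({"DNA": _profile_from(df)}, small_dataset.env)
        rich = out[out["response"] == "richness"]
        assert rich["rho"].isna().all()
        assert (rich["note"] != "").all()

    def test_planted_latitude_trend_detected_null_not(self, small_dataset):
        samples = [s for s in small_dataset.counts.sample_ids if s.endswith("dna")]
        env = small_dataset.env.aligned_to(samples)
        lat = env.data["latitude"].to_numpy()
        # diversity constructed to decline along latitude
        df = pd.DataFrame({"richness": 900 - 5 * lat,
                           "shannon": 6 - 0.01 * lat,
                           "faith_pd": 500 - 1 * lat,
                           "coverage": np.linspace(80, 95, 9)}, index=samples)
        out = alpha_env_screen({"DNA": _profile_from(df)}, small_dataset.env)
        row = out[(out["response"] == "shannon") & (out["property"] == "latitude")]
        assert bool(row["significant"].iloc[0])
        null_rows = out[out["property"] == "null_property"]
        assert not null_rows[null_rows["response"] == "shannon"]["significant"].iloc[0]

    def test_shuffling_env_rows_changes_nothing(self, small_dataset):
        samples = [s for s in small_dataset.counts.sample_ids if s.endswith("dna")]
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"richness": rng.integers(400, 900, 9).astype(float),
                           "shannon": rng.uniform(5, 6, 9),
                           "faith_pd": rng.uniform(380, 520, 9),
                           "coverage": rng.uniform(80, 95, 9)}, index=samples)
        env = small_dataset.env
        shuffled = EnvTable(env.data.sample(frac=1, random_state=5),
                            fraction=env.fraction)
        a = alpha_env_screen({"DNA": _profile_from(df)}, env)
        b = alpha_env_screen({"DNA": _profile_from(df)}, shuffled)
        pd.testing.assert_frame_equal(a, b)


class TestBetaScreen:
    def test_shape_and_fraction_separation(self, small_dataset):
        out = beta_env_screen(
            small_dataset.counts, small_dataset.env, small_dataset.tree,
            depths={"DNA": 9058, "RNA": 4941}, rarefactions=2, n_perm=19, seed=0,
            measures=("bray_weighted", "unifrac_weighted"),
        )
        n_props = len(small_dataset.env.properties)
        assert len(out) == 2 * n_props * 2  # measures x properties x fractions
        assert set(out["fraction"]) == {"DNA", "RNA"}
        # RNA arm lost its sub-threshold library
        assert out.loc[out["fraction"] == "RNA", "n"].max() == 8

    def test_missing_covariate_drops_samples_for_that_property_only(self, small_dataset):
        env = small_dataset.env
        data = env.data.copy()
        data.loc[data.index[0], "toc"] = np.nan
        env2 = EnvTable(data, fraction=env.fraction)
        out = beta_env_screen(
            small_dataset.counts, env2, None, depths={"DNA": 9058, "RNA": 4941},
            rarefactions=1, n_perm=9, seed=0, measures=("bray_weighted",),
        )
        dna = out[out["fraction"] == "DNA"].set_index("property")
        assert dna.loc["toc", "n"] == 8
        assert dna.loc["latitude", "n"] == 9

    def test_unifrac_without_tree_fails_fast(self, small_dataset):
        with pytest.raises(ValueError, match="tree"):
            beta_env_screen(small_dataset.counts, small_dataset.env, None,
                            depths={"DNA": 9058, "RNA": 4941},
                            rarefactions=1, n_perm=9, seed=0)


class TestFunctionScreen:
    def test_shape_one_row_per_property_and_fraction(self, small_dataset):
        out = function_screen(small_dataset.functions, small_dataset.env,
                              n_perm=19, seed=0)
        n_props = len(small_dataset.env.properties)
        assert len(out) == 2 * n_props
        assert set(out["measure"]) == {"bray_weighted"}

    def test_identical_profiles_give_zero_f(self, small_dataset):
        ids = small_dataset.functions.sample_ids
        flat = FunctionTable(pd.DataFrame(np.ones((len(ids), 4)) / 4, index=ids,
                                          columns=list("wxyz")))
        out = function_screen(flat, small_dataset.env, n_perm=19, seed=0)
        assert np.allclose(out["F"], 0.0)
        assert not out["significant"].any()

    def test_chlorophyll_signal_passes_through_linear_readout(self):
        from benthodiv.synthetic import SyntheticConfig, simulate_dataset
        ds = simulate_dataset(SyntheticConfig(seed=41, effect_size_chl=1.5))
        out = function_screen(ds.functions, ds.env, n_perm=99, seed=1)
        row = out[(out["property"] == "chlorophyll_sum") & (out["fraction"] == "DNA")]
        assert bool(row["significant"].iloc[0])
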