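import warnings

import numpy as np
import pandas as pd
import pytest

import ivforest as iv
from ivforest.forest import ForestParams
from ivforest.instrumental import leaf_wald
from ivforest.strata import TrialDataset
from ivforest.synthgen import SynthConfig, generate, make_config


class TestLeafWald:
    def test_identity_effect(self):
        rng = np.random.default_rng(0)
        z = rng.integers(0, 2, 100).astype(float) - 0.5
        d = z + 0.1 * rng.random(100)
        assert leaf_wald(d, d, z) == pytest.approx(1.0, abs=1e-12)

    def test_grouped_2009_marginals(self, grouped_2009_prenatal):
        y, d, z = grouped_2009_prenatal
        # oracle: hand Wald arithmetic, (0.700-0.644) / (512/1037 - 99/1028)
        itt = 0.700 - 0.644
        first = 512 / 1037 - 99 / 1028
        assert leaf_wald(y, d, z) == pytest.approx(itt / first, abs=1e-12)
        assert leaf_wald(y, d, z) == pytest.approx(0.141, abs=1e-3)

    def test_orthogonal_instrument_degenerate(self):
        z = np.tile([0.5, -0.5], 10)
        d = np.tile([1.0, 1.0, -1.0, -1.0], 5)  # Cov(d, z) = 0 exactly
        assert np.isnan(leaf_wald(np.ones(20), d, z))

    def test_short_vectors_error(self):
        with pytest.raises(ValueError):
            leaf_wald([1.0], [1.0], [1.0])

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        y, d, z = rng.random(50), rng.random(50), rng.integers(0, 2, 50).astype(float)
        base = leaf_wald(y, d, z)
        assert leaf_wald(3.0 * y, d, z) == pytest.approx(3.0 * base, rel=1e-12)


class TestResidualise:
    def test_perfect_outcome_model_zeroes_residual(self, homog4000):
        ds = homog4000["ds"]
        nu = iv.NuisanceEstimates(
            m_hat=ds.y.copy(), e_hat=np.full(ds.n, 0.5), g_hat=np.full(ds.n, 0.5),
            m_features=[], e_features=[], g_features=[])
        yr, dr, zr = iv.residualise(ds, nu)
        assert np.allclose(yr, 0.0)
        assert set(np.unique(zr)) <= {-0.5, 0.5}

    def test_elementwise_arithmetic(self):
        ds = TrialDataset(
            y=np.array([1.0, 0.0, 1.0]), d=np.array([1, 0, 1]),
            z=np.array([1, 0, 0]), x=pd.DataFrame({"a": [0, 1, 0]}))
        nu = iv.NuisanceEstimates(
            m_hat=np.array([0.5, 0.25, 0.75]), e_hat=np.array([0.6, 0.3, 0.5]),
            g_hat=np.array([0.5, 0.5, 0.5]),
            m_features=[], e_features=[], g_features=[])
        yr, dr, zr = iv.residualise(ds, nu)
        np.testing.assert_allclose(yr, [0.5, -0.25, 0.25])
        np.testing.assert_allclose(dr, [0.4, -0.3, 0.5])
        np.testing.assert_allclose(zr, [0.5, -0.5, -0.5])

    def test_length_mismatch_errors(self, homog4000):
        nu = iv.NuisanceEstimates(
            m_hat=np.zeros(3), e_hat=np.zeros(3), g_hat=np.zeros(3),
            m_features=[], e_features=[], g_features=[])
        with pytest.raises(ValueError):
            iv.residualise(homog4000["ds"], nu)


class TestNuisances:
    def test_instrument_propensity_near_half(self, homog4000):
        assert 0.45 <= homog4000["nu"].g_hat.mean() <= 0.55

    def test_supply_columns_never_split_treatment_propensity(self, homog4000):
        nu, ds = homog4000["nu"], homog4000["ds"]
        e_forest = nu.forests["e"]
        assert not set(nu.e_features) & set(ds.supply_tags)
        used = {
            e_forest.feature_names[f]
            for tree in e_forest.trees for f in tree.feature if f >= 0
        }
        assert not used & set(ds.supply_tags)

    def test_constant_outcome_gives_constant_m(self):
        rng = np.random.default_rng(3)
        n = 200
        ds = TrialDataset(
            y=np.full(n, 1.0), d=rng.integers(0, 2, n), z=rng.integers(0, 2, n),
            x=pd.DataFrame({"a": rng.integers(0, 2, n)}))
        nu = iv.estimate_nuisances(ds, ForestParams(num_trees=10, seed=1),
                                   exclude_supply_from_e=False)
        assert np.allclose(nu.m_hat, 1.0)

    def test_untagged_dataset_with_flag_errors(self):
        rng = np.random.default_rng(4)
        ds = TrialDataset(
            y=rng.random(50), d=rng.integers(0, 2, 50), z=rng.integers(0, 2, 50),
            x=pd.DataFrame({"a": rng.integers(0, 2, 50)}))
        with pytest.raises(ValueError, match="supply"):
            iv.estimate_nuisances(ds, ForestParams(num_trees=5, seed=1))

    def test_propensities_respect_clipping_band(self, planted4000):
        nu = planted4000["nu"]
        for v in (nu.e_hat, nu.g_hat):
            assert v.min() >= 0.01 and v.max() <= 0.99


def _oracle_nuisances(ds):
    n = ds.n
    return iv.NuisanceEstimates(
        m_hat=np.full(n, ds.y.mean()), e_hat=np.full(n, max(ds.d.mean(), 0.01)),
        g_hat=np.clip(np.full(n, ds.z.mean()), 0.01, 0.99),
        m_features=[], e_features=[], g_features=[])


class TestIVForest:
    def test_single_leaf_forest_equals_global_wald(self):
        sds = generate(make_config("planted_binary", n=500, seed=3))
        ds = sds.dataset
        nu = _oracle_nuisances(ds)
        params = ForestParams(num_trees=5, min_node_size=500, sample_fraction=1.0,
                              honesty=False, seed=2)
        model = iv.fit_iv_forest(ds, nu, params)
        yr, dr, zr = iv.residualise(ds, nu)
        expected = leaf_wald(yr, dr, zr)
        clates = iv.predict_clate(model)
        assert np.abs(clates.tau - expected).max() < 1e-8

    def test_planted_contrast_recovered(self, planted4000):
        tau = planted4000["clates"].tau
        x1 = planted4000["ds"].x["x1"].to_numpy()
        contrast = tau[x1 == 1].mean() - tau[x1 == 0].mean()
        assert contrast >= 0.2  # truth is 0.4

    def test_homogeneous_clates_concentrate(self):
        sds = generate(make_config("homogeneous", n=4000, seed=5))
        ds = sds.dataset
        params = ForestParams(num_trees=300, min_node_size=200, seed=6)
        nu = iv.estimate_nuisances(ds, params)
        model = iv.fit_iv_forest(ds, nu, params)
        clates = iv.predict_clate(model)
        assert clates.tau.std() < 0.1

    def test_homogeneity_contraction_with_sample_size(self):
        """Mean CLATE dispersion (5 fixed seeds per n) shrinks as n doubles."""
        mean_sd = []
        for n in (1000, 2000, 4000):
            sd = []
            for seed in range(5):
                sds = generate(make_config("homogeneous", n=n, seed=40 + seed))
                ds = sds.dataset
                params = ForestParams(num_trees=150, min_node_size=n // 20, seed=8)
                nu = iv.estimate_nuisances(ds, params)
                model = iv.fit_iv_forest(ds, nu, params)
                sd.append(iv.predict_clate(model).tau.std())
            mean_sd.append(np.mean(sd))
        assert mean_sd[0] > mean_sd[1] > mean_sd[2]

    def test_residual_means_near_zero(self, homog4000):
        model = homog4000["model"]
        bound = 3.0 / np.sqrt(model.n_train)
        for r in (model.yr, model.dr, model.zr):
            assert abs(r.mean()) < bound

    def test_min_node_size_n_gives_single_leaf_trees(self, homog4000):
        ds, nu = homog4000["ds"], homog4000["nu"]
        params = ForestParams(num_trees=3, min_node_size=ds.n, seed=9)
        model = iv.fit_iv_forest(ds, nu, params)
        assert all((t.feature == -1).all() for t in model.trees)

    def test_weak_instrument_errors(self):
        cfg = SynthConfig(n=300, strata_probs=(0.0, 0.0, 1.0),
                          covariate_spec=(("a", "binary", 0.5),), seed=4)
        ds = generate(cfg).dataset  # never-takers only: D identically 0
        with pytest.raises(ValueError, match="weak instrument"):
            iv.fit_iv_forest(ds, _oracle_nuisances(ds),
                             ForestParams(num_trees=3, seed=1))

    def test_new_profile_schema_mismatch_errors(self, planted4000):
        model = planted4000["model"]
        bad = pd.DataFrame({"wrong": [0, 1]})
        with pytest.raises(ValueError, match="schema"):
            iv.predict_clate(model, bad)

    def test_oob_prediction_deterministic(self, homog4000):
        ds, nu, params = homog4000["ds"], homog4000["nu"], homog4000["params"]
        again = iv.predict_clate(iv.fit_iv_forest(ds, nu, params))
        np.testing.assert_array_equal(again.tau, homog4000["clates"].tau)


class TestTune:
    def test_single_point_grid_returned(self, homog4000):
        ds, nu = homog4000["ds"], homog4000["nu"]
        only = ForestParams(num_trees=20, seed=3)
        result = iv.tune(ds, nu, [only])
        assert result.best == only
        assert len(result.scores) == 1

    def test_full_pool_beats_noise_only_pool_on_planted_data(self, planted4000):
        ds, nu = planted4000["ds"], planted4000["nu"]
        noise_cols = tuple(j for j, c in enumerate(ds.covariate_names) if c != "x1")
        narrow = ForestParams(num_trees=60, feature_subset=noise_cols, seed=5)
        full = ForestParams(num_trees=60, seed=5)
        result = iv.tune(ds, nu, [narrow, full])
        assert result.best == full

    def test_identical_points_tie_break_to_first(self, homog4000):
        ds, nu = homog4000["ds"], homog4000["nu"]
        a = ForestParams(num_trees=15, seed=4)
        b = ForestParams(num_trees=15, seed=4)
        result = iv.tune(ds, nu, [a, b])
        assert result.scores.loc[0, "loss"] == result.scores.loc[1, "loss"]
        assert result.best is a

    def test_empty_grid_errors(self, homog4000):
        with pytest.raises(ValueError, match="empty"):
            iv.tune(homog4000["ds"], homog4000["nu"], [])
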