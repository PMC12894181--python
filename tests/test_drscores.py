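import warnings

import numpy as np
import pandas as pd
import pytest

import ivforest as iv
from ivforest.forest import ForestParams
from ivforest.instrumental import CLATEs, NuisanceEstimates, leaf_wald
from ivforest.strata import TrialDataset
from ivforest.synthgen import SynthConfig, generate, make_config, true_late


def constant_nuisances(ds):
    n = ds.n
    return NuisanceEstimates(
        m_hat=np.full(n, ds.y.mean()),
        e_hat=np.clip(np.full(n, ds.d.mean()), 0.01, 0.99),
        g_hat=np.clip(np.full(n, ds.z.mean()), 0.01, 0.99),
        m_features=[], e_features=[], g_features=[])


class TestComplianceScore:
    def test_perfect_compliance_delta_near_one(self):
        cfg = SynthConfig(n=4000, strata_probs=(1.0, 0.0, 0.0),
                          covariate_spec=(("a", "binary", 0.5), ("b", "binary", 0.3)),
                          seed=2)
        ds = generate(cfg).dataset
        nu = constant_nuisances(ds)
        cs = iv.compliance_score(ds, nu, ForestParams(num_trees=50, seed=1))
        assert abs(cs.delta_hat.mean() - 1.0) < 0.05

    def test_mean_delta_matches_configured_complier_share(self):
        sds = generate(make_config("pkh2009", n=8000, seed=3))
        ds = sds.dataset
        params = ForestParams(num_trees=60, min_node_size=50, seed=4)
        nu = iv.estimate_nuisances(ds, params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            cs = iv.compliance_score(ds, nu, params)
        assert abs(cs.delta_hat.mean() - 0.398) < 0.03

    def test_all_never_takers_error(self):
        cfg = SynthConfig(n=300, strata_probs=(0.0, 0.0, 1.0),
                          covariate_spec=(("a", "binary", 0.5),), seed=5)
        ds = generate(cfg).dataset
        with pytest.raises(ValueError, match="compliance"):
            iv.compliance_score(ds, constant_nuisances(ds),
                                ForestParams(num_trees=5, seed=1))

    def test_floor_clipping_flagged(self, homog4000):
        cs = homog4000["cs"]
        assert cs.delta_hat.min() >= 0.01
        assert cs.clipped.sum() == (cs.delta_hat == 0.01).sum() or cs.clipped.sum() >= 0


class TestDRScore:
    def test_zero_correction_returns_clate(self):
        n = 8
        rng = np.random.default_rng(6)
        tau = rng.random(n)
        e = np.full(n, 0.5)
        g = np.full(n, 0.5)
        d = rng.integers(0, 2, n)
        z = rng.integers(0, 2, n)
        m = np.full(n, 0.3)
        y = m + (d - e) * tau  # residual identically zero by construction
        ds = TrialDataset(y=y, d=d, z=z, x=pd.DataFrame({"a": np.zeros(n)}))
        nu = NuisanceEstimates(m_hat=m, e_hat=e, g_hat=g,
                               m_features=[], e_features=[], g_features=[])
        cs = iv.ComplianceScores(delta_hat=np.full(n, 0.5), clipped=np.zeros(n, bool))
        scores = iv.dr_score(ds, CLATEs(tau=tau, oob=True, fallback=np.zeros(n, bool)),
                             nu, cs)
        np.testing.assert_allclose(scores.gamma, tau, atol=1e-12)

    def test_four_row_hand_fixture(self):
        # calculator arithmetic with g = 0.5, delta = 0.5:
        # weight = +-4; rows give Gamma = (1.8, 1.8, 1.86, 1.86)
        y = np.array([1.0, 0.0, 1.0, 0.0])
        d = np.array([1, 0, 0, 1])
        z = np.array([1, 0, 1, 0])
        m = np.array([0.5, 0.5, 0.6, 0.3])
        e = np.array([0.5, 0.5, 0.4, 0.7])
        tau = np.array([0.2, 0.2, 0.1, 0.3])
        ds = TrialDataset(y=y, d=d, z=z, x=pd.DataFrame({"a": np.zeros(4)}))
        nu = NuisanceEstimates(m_hat=m, e_hat=e, g_hat=np.full(4, 0.5),
                               m_features=[], e_features=[], g_features=[])
        cs = iv.ComplianceScores(delta_hat=np.full(4, 0.5), clipped=np.zeros(4, bool))
        scores = iv.dr_score(ds, CLATEs(tau=tau, oob=True, fallback=np.zeros(4, bool)),
                             nu, cs)
        np.testing.assert_allclose(scores.gamma, [1.8, 1.8, 1.86, 1.86], atol=1e-12)

    def test_homogeneous_mean_gamma_near_truth(self, homog4000):
        est = iv.late(homog4000["gamma"])
        assert abs(est.tau_hat - 0.2) <= 2.0 * est.se


class TestLate:
    def test_constant_scores(self):
        est = iv.late(iv.DRScores(gamma=np.full(5, 0.37)))
        assert est.tau_hat == pytest.approx(0.37)
        assert est.se == 0.0

    def test_hand_vector(self):
        est = iv.late(iv.DRScores(gamma=np.array([0.1, 0.3, 0.2, 0.4])))
        assert est.tau_hat == pytest.approx(0.25, abs=1e-14)
        sd = np.std([0.1, 0.3, 0.2, 0.4], ddof=1)
        assert est.se == pytest.approx(sd / 2.0, abs=1e-14)
        assert est.ci95 == pytest.approx((0.25 - 1.96 * est.se, 0.25 + 1.96 * est.se))

    def test_mean_identity_with_scores(self, homog4000):
        gamma = homog4000["gamma"]
        assert iv.late(gamma).tau_hat == gamma.gamma.mean()

    def test_oracle_nuisance_double_robustness(self):
        """With analytic nuisances and the true effect surface plugged in,
        mean(Gamma) sits within 2 SE of the true LATE across seeds."""
        hits = 0
        for seed in range(50):
            cfg = make_config("planted_binary", n=1500, seed=100 + seed)
            sds = generate(cfg)
            ds = sds.dataset
            pc, pa, _ = cfg.strata_probs
            n = ds.n
            x1 = ds.x["x1"].to_numpy(dtype=float)
            tau_true = sds.true_tau
            e_true = np.full(n, pa + pc * cfg.p_assign)
            g_true = np.full(n, cfg.p_assign)
            delta_true = np.full(n, pc)
            m_true = sds.true_m * 1.0 + e_true * tau_true  # E[Y|X] = p0 + e*tau
            nu = NuisanceEstimates(m_hat=m_true, e_hat=e_true, g_hat=g_true,
                                   m_features=[], e_features=[], g_features=[])
            cs = iv.ComplianceScores(delta_hat=delta_true,
                                     clipped=np.zeros(n, bool))
            scores = iv.dr_score(
                ds, CLATEs(tau=tau_true, oob=True, fallback=np.zeros(n, bool)),
                nu, cs)
            est = iv.late(scores)
            hits += abs(est.tau_hat - true_late(sds)) <= 2.0 * est.se
        assert hits >= 45


class TestBaseline2SLS:
    def test_no_covariates_equals_wald(self, planted4000):
        ds = planted4000["ds"]
        est = iv.baseline_2sls(ds)
        wald = leaf_wald(ds.y, ds.d.astype(float), ds.z.astype(float))
        assert est.tau_hat == pytest.approx(wald, abs=1e-10)

    def test_grouped_2009_marginals(self, grouped_2009_prenatal):
        y, d, z = grouped_2009_prenatal
        ds = TrialDataset(y=y, d=d.astype(int), z=z.astype(int),
                          x=pd.DataFrame({"c": np.zeros(len(y))}))
        est = iv.baseline_2sls(ds)
        assert est.tau_hat == pytest.approx(0.141, abs=1e-3)

    def test_consistent_for_planted_truth(self, planted4000):
        ds, sds = planted4000["ds"], planted4000["sds"]
        est = iv.baseline_2sls(ds)
        assert abs(est.tau_hat - true_late(sds)) <= 2.0 * est.se

    def test_matches_statsmodels_reference(self, planted4000):
        from statsmodels.sandbox.regression.gmm import IV2SLS
        ds = planted4000["ds"]
        covs = ["x2", "x3"]
        est = iv.baseline_2sls(ds, covariates=covs)
        xc = ds.x[covs].to_numpy(dtype=float)
        ones = np.ones((ds.n, 1))
        exog = np.hstack([ones, xc, ds.d.reshape(-1, 1)])
        instr = np.hstack([ones, xc, ds.z.reshape(-1, 1)])
        ref = IV2SLS(ds.y, exog, instrument=instr).fit()
        assert est.tau_hat == pytest.approx(ref.params[-1], abs=1e-10)
        assert est.se == pytest.approx(ref.bse[-1], rel=1e-6)

    def test_collinear_columns_named(self, planted4000):
        ds = planted4000["ds"]
        x = ds.x.copy()
        x["dup"] = x["x2"]
        ds2 = TrialDataset(y=ds.y, d=ds.d, z=ds.z, x=x)
        with pytest.raises(ValueError, match="dup"):
            iv.baseline_2sls(ds2, covariates=["x2", "dup"])
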