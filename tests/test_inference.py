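"""Distributional tests of the sampler against independent oracles."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bridgetox.inference import (
    McmcSettings,
    PosteriorDraws,
    RiskSamples,
    component_probabilities,
    effective_draws,
    fit,
    interval_probabilities,
    map_prior_risk,
    predictive_dlt_risk,
    split_rhat,
    summarize,
)
from bridgetox.model_core import (
    AnimalStudyData,
    ExchangeabilityWeights,
    HumanTrialData,
    ModelConfig,
    default_config,
    DEFAULT_TRANSLATION,
)
from bridgetox.trial_sim import DOSE_PANEL, preset_weights


def mcse(x):
    return x.std() / np.sqrt(effective_draws(x))


class TestSettings:
    def test_validation(self):
        with pytest.raises(ValueError):
            McmcSettings(chains=0)
        with pytest.raises(ValueError):
            McmcSettings(iterations=100, burnin=100)

    def test_draw_count(self, config_robust_only, fast_mcmc):
        d = fit(config_robust_only, [], [], fast_mcmc)
        n = fast_mcmc.draws_per_chain
        assert d.n_chains == fast_mcmc.chains and d.n_draws == n
        for arr in d.params.values():
            assert arr.shape == (fast_mcmc.chains, n)


class TestPriorRecovery:
    def test_robust_only_gamma_matches_bvn(self, config_robust_only, fast_mcmc):
        d = fit(config_robust_only, [], [], fast_mcmc)
        ne = config_robust_only.nonex[0]
        for name, mean, sd in (
            ("gamma1[1]", ne.mean[0], np.sqrt(ne.cov[0, 0])),
            ("gamma2[1]", ne.mean[1], np.sqrt(ne.cov[1, 1])),
        ):
            x = d.params[name]
            assert abs(x.mean() - mean) < 3 * mcse(x)
            assert x.std() == pytest.approx(sd, rel=0.05)

    def test_eps_prior_symmetric(self, config_robust_only, fast_mcmc):
        d = fit(config_robust_only, [], [], fast_mcmc)
        e = d.stacked("eps[1]")
        assert abs(e.mean() - 1.0) < 3 * mcse(d.params["eps[1]"])
        assert abs((e < 1.0).mean() - 0.5) < 0.02
        assert e.min() > 0.0 and e.max() < 2.0

    def test_half_normal_and_delta_priors(self, config_t1, fast_mcmc):
        d = fit(config_t1, [], [], fast_mcmc)
        hp = config_t1.hierarchy
        hn_mean = np.sqrt(2 / np.pi)
        for name, scale in (("tau1", hp.z1), ("tau3", hp.z3), ("sigma1", hp.c1)):
            x = d.params[name]
            assert abs(x.mean() - scale * hn_mean) < 4 * mcse(x)
        ld = np.log(d.stacked("delta[rat]"))
        tp = DEFAULT_TRANSLATION["rat"]
        assert abs(ld.mean() - tp.meanlog) < 4 * mcse(np.log(d.params["delta[rat]"]))
        assert ld.std() == pytest.approx(tp.sdlog, rel=0.1)


class TestComponentProbabilities:
    def test_degenerate_robust(self, config_robust_only, fast_mcmc):
        d = fit(config_robust_only, [], [], fast_mcmc)
        probs = component_probabilities(d, 1)
        assert np.allclose(probs, [0.0, 1.0])

    def test_prior_weights_recovered(self, config_t1):
        d = fit(config_t1, [], [], McmcSettings(chains=2, iterations=30000, burnin=2000, seed=9))
        probs = component_probabilities(d, 1)
        assert probs.sum() == pytest.approx(1.0)
        assert np.allclose(probs, [0.2, 0.6, 0.0, 0.2], atol=0.03)

    def test_two_component_marginal_likelihood_ratio(self):
        """Posterior z-probabilities vs brute-force marginal likelihoods.

        Two non-overlapping components (species exchangeable vs robust)
        with fixed hyperparameters; the marginal likelihood of each is
        computed by 2-D quadrature and combined with the prior weights.
        """
        study = AnimalStudyData("s", "monkey", [5.0], [1], [0])  # anchors the species mean
        human = [HumanTrialData(1, [5.0], [12], [5])]
        w = ExchangeabilityWeights({"monkey": 0.5}, human=0.0, robust=0.5)
        config = ModelConfig(
            species=("monkey",),
            translation={"monkey": DEFAULT_TRANSLATION["monkey"]},
            weights=(w,),
            fixed_eps=(True,),
        )
        mu = np.array([[-2.5, 0.0]])
        psi = (0.4, 0.2, 0.0)
        delta = np.array([1.0])
        d = fit(
            config, [study], human,
            McmcSettings(chains=2, iterations=40000, burnin=5000, seed=21),
            fixed={"mu_species": mu, "psi": psi, "delta": delta},
        )
        probs = component_probabilities(d, 1)

        def marginal(mean, cov):
            g1 = np.linspace(mean[0] - 6 * np.sqrt(cov[0][0]), mean[0] + 6 * np.sqrt(cov[0][0]), 301)
            g2 = np.linspace(mean[1] - 6 * np.sqrt(cov[1][1]), mean[1] + 6 * np.sqrt(cov[1][1]), 301)
            G1, G2 = np.meshgrid(g1, g2, indexing="ij")
            dens = stats.multivariate_normal.pdf(np.dstack([G1, G2]), mean, np.array(cov))
            eta = G1  # dose = d_ref so the log term vanishes
            lik = np.exp(5 * eta - 12 * np.logaddexp(0, eta))
            dg1, dg2 = g1[1] - g1[0], g2[1] - g2[0]
            return float((dens * lik).sum() * dg1 * dg2)

        cov_exch = [[0.16, 0.0], [0.0, 0.04]]  # fixed psi, zero correlation
        m_exch = marginal(mu[0], cov_exch)
        ne = config.nonex[0]
        m_rob = marginal(ne.mean, ne.cov)
        want = 0.5 * m_exch / (0.5 * m_exch + 0.5 * m_rob)
        assert probs[0] == pytest.approx(want, abs=0.03)

    def test_unknown_subgroup_raises(self, config_robust_only, fast_mcmc):
        d = fit(config_robust_only, [], [], fast_mcmc)
        with pytest.raises(ValueError):
            component_probabilities(d, 2)


class TestQuadratureOracle:
    def test_single_study_reduction(self):
        study = AnimalStudyData("s1", "monkey", [1, 10, 30, 100], [6, 6, 6, 6], [0, 1, 3, 5])
        mu = np.array([[-1.0, 0.2]])
        psi = (0.6, 0.3, 0.2)
        delta = np.array([0.32])
        cfg = ModelConfig(
            species=("monkey",),
            translation={"monkey": DEFAULT_TRANSLATION["monkey"]},
            weights=(ExchangeabilityWeights({"monkey": 1.0}),),
        )
        d = fit(
            cfg, [study], [],
            McmcSettings(chains=2, iterations=20000, burnin=2000, seed=3),
            fixed={"mu_species": mu, "psi": psi, "delta": delta},
        )
        g1 = np.linspace(mu[0, 0] - 5 * psi[0], mu[0, 0] + 5 * psi[0], 401)
        g2 = np.linspace(mu[0, 1] - 5 * psi[1], mu[0, 1] + 5 * psi[1], 401)
        G1, G2 = np.meshgrid(g1, g2, indexing="ij")
        z1 = (G1 - mu[0, 0]) / psi[0]
        z2 = (G2 - mu[0, 1]) / psi[1]
        r = psi[2]
        lp = -(z1**2 - 2 * r * z1 * z2 + z2**2) / (2 * (1 - r**2))
        for dd, nn, rr in zip(study.doses, study.n, study.r):
            eta = G1 + np.exp(G2) * np.log(delta[0] * dd / 5.0)
            lp += rr * eta - nn * np.logaddexp(0, eta)
        w = np.exp(lp - lp.max())
        w /= w.sum()
        for name, G in (("theta1[s1]", G1), ("theta2[s1]", G2)):
            x = d.params[name]
            quad_mean = float((w * G).sum())
            assert abs(x.mean() - quad_mean) < 3 * mcse(x)
            quad_var = float((w * G**2).sum() - quad_mean**2)
            assert x.var() == pytest.approx(quad_var, rel=0.1)


class TestPredictiveRisk:
    def test_degenerate_draws_quarter_risk(self, config_robust_only):
        n = 50
        params = {
            "gamma1[1]": np.full((1, n), -np.log(3.0)),
            "gamma2[1]": np.zeros((1, n)),
            "eps[1]": np.ones((1, n)),
        }
        d = PosteriorDraws(
            params=params, z=np.ones((1, n, 1), dtype=int),
            config=config_robust_only, settings=McmcSettings(chains=1, iterations=n + 1, burnin=1),
        )
        risks = predictive_dlt_risk(d, 1, [5.0])
        assert np.allclose(risks.samples, 0.25)

    def test_monotone_risk_per_draw(self, config_t1, fast_mcmc):
        d = fit(config_t1, [], [], fast_mcmc)
        risks = predictive_dlt_risk(d, 1, DOSE_PANEL)
        assert np.all(np.diff(risks.samples, axis=1) >= 0)
        assert risks.samples.min() >= 0 and risks.samples.max() <= 1

    def test_robust_isolation_from_animal_data(self, config_robust_only, animal_fixture):
        """With w_R = 1 the predictive ignores animal data entirely."""
        cfg = ModelConfig(
            species=("rat", "monkey"),
            translation=dict(DEFAULT_TRANSLATION),
            weights=(ExchangeabilityWeights({"rat": 0.0, "monkey": 0.0}, robust=1.0),),
        )
        s1 = McmcSettings(chains=2, iterations=8000, burnin=1000, seed=5)
        without = fit(cfg, [], [], s1)
        with_animal = fit(cfg, animal_fixture, [], s1)
        for name in ("gamma1[1]", "gamma2[1]"):
            a, b = without.params[name], with_animal.params[name]
            tol = 3 * np.hypot(mcse(a), mcse(b))
            assert abs(a.mean() - b.mean()) < tol
            assert a.std() == pytest.approx(b.std(), rel=0.1)

    def test_map_prior_matches_in_fit_construction(self, animal_fixture):
        """Fresh-draw MAP construction vs a data-free subgroup in the fit."""
        w = preset_weights("A", 1)
        cfg1 = default_config([w])
        s = McmcSettings(chains=2, iterations=10000, burnin=2000, seed=13)
        d1 = fit(cfg1, animal_fixture, [], s)
        in_fit = predictive_dlt_risk(d1, 1, DOSE_PANEL)
        cfg0 = default_config([ExchangeabilityWeights({"rat": 1.0})])  # placeholder subgroup
        d0 = fit(cfg0, animal_fixture, [], s)
        fresh = map_prior_risk(d0, w, DOSE_PANEL, seed=99)
        for j in range(len(DOSE_PANEL)):
            a, b = in_fit.samples[:, j], fresh.samples[:, j]
            se_a = a.std() / np.sqrt(effective_draws(a.reshape(2, -1)))
            se_b = b.std() / np.sqrt(effective_draws(b.reshape(2, -1)))
            assert abs(a.mean() - b.mean()) < max(3 * np.hypot(se_a, se_b), 0.02)

    def test_panel_validation(self, config_robust_only, fast_mcmc):
        d = fit(config_robust_only, [], [], fast_mcmc)
        with pytest.raises(ValueError):
            predictive_dlt_risk(d, 1, [])
        with pytest.raises(ValueError):
            predictive_dlt_risk(d, 1, [5.0, 1.0])
        with pytest.raises(ValueError):
            predictive_dlt_risk(d, 3, [1.0])


class TestIntervalProbabilities:
    def test_all_under(self):
        r = RiskSamples(doses=[1.0], samples=np.full((100, 1), 0.10))
        assert np.allclose(interval_probabilities(r), [[1.0, 0.0, 0.0]])

    def test_boundary_is_overdose(self):
        r = RiskSamples(doses=[1.0], samples=np.full((100, 1), 0.33))
        assert np.allclose(interval_probabilities(r), [[0.0, 0.0, 1.0]])

    def test_uniform_closed_form(self):
        rng = np.random.default_rng(0)
        r = RiskSamples(doses=[1.0], samples=rng.random((200000, 1)))
        iv = interval_probabilities(r)[0]
        assert iv == pytest.approx([0.16, 0.17, 0.67], abs=0.005)
        assert iv.sum() == pytest.approx(1.0)

    def test_rows_sum_to_one(self, config_t1, fast_mcmc):
        d = fit(config_t1, [], [], fast_mcmc)
        iv = interval_probabilities(predictive_dlt_risk(d, 1, DOSE_PANEL))
        assert np.allclose(iv.sum(axis=1), 1.0)
        assert np.all(iv >= 0)

    def test_cutoff_validation(self):
        r = RiskSamples(doses=[1.0], samples=np.full((10, 1), 0.5))
        with pytest.raises(ValueError):
            interval_probabilities(r, under_cut=0.5, over_cut=0.3)

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            RiskSamples(doses=[1.0], samples=np.empty((0, 1)))


class TestSummarize:
    def test_constant_samples(self):
        r = RiskSamples(doses=[1.0, 2.0], samples=np.full((50, 2), 0.3))
        s = summarize(r)
        assert np.allclose(s["mean"], 0.3)
        assert np.allclose(s["median"], 0.3)
        assert np.allclose(s["sd"], 0.0)

    def test_three_point_mean(self):
        r = RiskSamples(doses=[1.0], samples=np.array([[0.1], [0.2], [0.3]]))
        assert summarize(r)["mean"].iloc[0] == pytest.approx(0.2)

    def test_independent_recomputation(self, config_t1, fast_mcmc):
        d = fit(config_t1, [], [], fast_mcmc)
        risks = predictive_dlt_risk(d, 1, DOSE_PANEL)
        s = summarize(risks)
        # recompute with a second routine (pandas describe / sort-based)
        df = pd.DataFrame(risks.samples, columns=risks.doses)
        assert np.allclose(s["mean"], df.mean().to_numpy())
        assert np.allclose(s["sd"], df.std().to_numpy())
        assert np.allclose(s["median"], df.quantile(0.5).to_numpy())
        assert np.allclose(s["q97.5"], df.quantile(0.975).to_numpy(), atol=1e-9)
        assert ((s["median"] >= risks.samples.min(0)) & (s["median"] <= risks.samples.max(0))).all()


class TestReproducibilityAndRecovery:
    def test_identical_seed_identical_draws(self, config_t1, animal_fixture):
        s = McmcSettings(chains=2, iterations=3000, burnin=500, seed=77)
        a = fit(config_t1, animal_fixture, [], s)
        b = fit(config_t1, animal_fixture, [], s)
        for name in a.params:
            assert np.array_equal(a.params[name], b.params[name])
        assert np.array_equal(a.z, b.z)

    def test_parameter_recovery_large_n(self):
        """Very large per-dose samples pin the intercept near the truth.

        The bridging factor is fixed at 1: the data only identify
        gamma1 + exp(gamma2)*log(eps), so a free eps leaves its prior
        spread in the intercept at any sample size.
        """
        cfg = ModelConfig(
            species=(), translation={},
            weights=(ExchangeabilityWeights({}, robust=1.0),),
            fixed_eps=(True,),
        )
        rng = np.random.default_rng(8)
        true_g = (-1.3, 0.1)
        doses = np.array([0.5, 1.0, 5.0, 10.0])
        p = 1 / (1 + np.exp(-(true_g[0] + np.exp(true_g[1]) * np.log(doses / 5.0))))
        n = np.full(4, 1000)
        r = rng.binomial(n, p)
        human = [HumanTrialData(1, doses, n, r)]
        d = fit(cfg, [], human, McmcSettings(chains=2, iterations=12000, burnin=2000, seed=4))
        assert abs(d.stacked("gamma1[1]").mean() - true_g[0]) < 0.1
        assert d.stacked("gamma1[1]").std() < 0.1

    def test_duplicate_subgroup_rejected(self, config_robust_only, fast_mcmc):
        human = [HumanTrialData(1, [1.0], [3], [0]), HumanTrialData(1, [2.0], [3], [1])]
        with pytest.raises(ValueError):
            fit(config_robust_only, [], human, fast_mcmc)

    def test_unknown_fixed_key_rejected(self, config_robust_only, fast_mcmc):
        with pytest.raises(ValueError):
            fit(config_robust_only, [], [], fast_mcmc, fixed={"nope": 1})


class TestDiagnostics:
    def test_split_rhat_iid_near_one(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((4, 2000))
        assert split_rhat(x) == pytest.approx(1.0, abs=0.01)

    def test_split_rhat_detects_divergent_chains(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((2, 2000))
        x[1] += 5.0
        assert split_rhat(x) > 2.0

    def test_effective_draws_iid(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((1, 20000))
        assert effective_draws(x) == pytest.approx(20000, rel=0.1)

    def test_effective_draws_autocorrelated(self):
        rng = np.random.default_rng(4)
        e = rng.standard_normal(20000)
        x = np.empty(20000)
        x[0] = e[0]
        for i in range(1, 20000):
            x[i] = 0.9 * x[i - 1] + e[i]
        # AR(1) with phi=0.9 has ess ~ n*(1-phi)/(1+phi) ~ n/19
        assert effective_draws(x[None, :]) == pytest.approx(20000 / 19, rel=0.3)
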