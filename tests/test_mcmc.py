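import numpy as np
import pytest
from scipy import integrate, special, stats as sps

from stmap.bayes_stmodel import (ModelSpec, PriorSpec, STModel, dic, fit_mcmc,
                                 pit, pit_histogram, poisson_loglik, waic)
from stmap.bayes_stmodel.mcmc import default_priors


def intercept_spec(var=100.0):
    return ModelSpec(spatial="none", temporal_structured="none",
                     temporal_iid="none", interaction="none",
                     priors={"alpha": PriorSpec("normal", (0.0, var))})


class TestModelSpec:
    def test_interaction_requires_structured_blocks(self):
        with pytest.raises(ValueError, match="interaction"):
            ModelSpec(spatial="iid", temporal_structured="ar1",
                      interaction="typeIV")
        with pytest.raises(ValueError, match="interaction"):
            ModelSpec(spatial="bym2", temporal_structured="none",
                      temporal_iid="iid", interaction="typeI")

    def test_every_precision_has_exactly_one_prior(self):
        spec = ModelSpec()
        assert set(spec.priors) == {"alpha", "tau_b", "omega", "tau_gamma",
                                    "rho", "tau_phi", "tau_delta"}

    def test_extraneous_priors_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            ModelSpec(spatial="none", temporal_structured="none",
                      temporal_iid="none", interaction="none",
                      priors={"tau_u": PriorSpec("loggamma", (1.0, 1.0))})

    def test_default_priors_match_configuration(self):
        pri = default_priors("bym", "rw1", "iid", "none")
        assert pri["tau_u"].family == "loggamma"
        assert "tau_b" not in pri


class TestLogPosterior:
    def test_loglik_at_theta_one(self):
        o = np.array([[3.0, 1.0], [0.0, 2.0]])
        e = np.array([[2.0, 1.5], [0.7, 2.2]])
        expected = float(np.sum(-e + o * np.log(e) - special.gammaln(o + 1)))
        assert poisson_loglik(o, e, np.zeros_like(o)) == pytest.approx(
            expected)

    def test_doubling_e_changes_loglik_by_olog2_minus_e(self):
        o = np.array([[3.0, 1.0], [4.0, 2.0]])
        e = np.array([[2.0, 1.5], [0.7, 2.2]])
        eta = np.zeros_like(o)
        diff = poisson_loglik(o, 2 * e, eta) - poisson_loglik(o, e, eta)
        assert diff == pytest.approx(float((o * np.log(2) - e).sum()))

    def test_bym2_at_omega_zero_is_iid_scaled(self, grid4, rng):
        o = np.ones((grid4.n, 2))
        e = np.ones((grid4.n, 2))
        m = STModel(o, e, ModelSpec(temporal_structured="ar1",
                                    interaction="none"), grid4)
        m.omega = 0.0
        m.tau_b = 4.0
        m.v = rng.normal(size=grid4.n)
        m.ustar = rng.normal(size=grid4.n)
        assert np.allclose(m.b(), m.v / 2.0)

    def test_rejects_tiny_expected_counts(self, grid4):
        o = np.zeros((grid4.n, 2))
        e = np.full((grid4.n, 2), 1e-12)
        with pytest.raises(ValueError, match="rejected"):
            STModel(o, e, ModelSpec(interaction="none",
                                    temporal_structured="ar1"), grid4)

    def test_zero_length_data_rejected(self):
        with pytest.raises(ValueError):
            fit_mcmc(np.empty((0, 0)), np.empty((0, 0)), intercept_spec(),
                     seed=1)


class TestQuadratureOracle:
    def test_single_cell_posterior_mean_matches_quadrature(self):
        # one area, one period, O=7, E=2, log theta = alpha ~ N(0, 100)
        o = np.array([[7.0]])
        e = np.array([[2.0]])
        spec = intercept_spec(var=100.0)

        def post(a):
            return np.exp(7 * a - 2 * np.exp(a)) * np.exp(-a * a / 200)

        z, _ = integrate.quad(post, -10, 10)
        theta_truth = integrate.quad(lambda a: np.exp(a) * post(a),
                                     -10, 10)[0] / z
        fit = fit_mcmc(o, e, spec, chains=2, iterations=6000, burn_in=1000,
                       thin=2, seed=42)
        draws = np.exp(fit.pooled("alpha"))
        mc_se = draws.std(ddof=1) / np.sqrt(fit.ess["alpha"])
        assert draws.mean() == pytest.approx(theta_truth, abs=3 * mc_se)

    def test_two_cell_iid_posterior_matches_quadrature(self, rng):
        # two independent areas sharing only the intercept; marginal
        # posterior of theta_1 checked against 1-D quadrature with
        # alpha fixed at 0 by a very tight prior
        o = np.array([[4.0], [9.0]])
        e = np.array([[3.0], [5.0]])
        from stmap.geo_weights import RegionGraph
        g = RegionGraph.from_edges(["a", "b"], [])
        spec = ModelSpec(spatial="iid", temporal_structured="none",
                         temporal_iid="none", interaction="none",
                         priors={"alpha": PriorSpec("normal", (0.0, 1e-12)),
                                 "tau_v": PriorSpec("loggamma",
                                                    (1e6, 1e6))})
        # tau_v ~ Gamma(1e6, 1e6) concentrates at 1: v_i ~ N(0,1)
        fit = fit_mcmc(o, e, spec, g, chains=2, iterations=6000,
                       burn_in=1000, thin=2, seed=17)

        def post(v):
            return np.exp(4 * v - 3 * np.exp(v)) * np.exp(-v * v / 2)

        z = integrate.quad(post, -8, 8)[0]
        truth = integrate.quad(lambda v: np.exp(v) * post(v), -8, 8)[0] / z
        draws = np.exp(fit.pooled("b")[:, 0])
        mc_se = draws.std(ddof=1) / np.sqrt(max(fit.ess.get("alpha", 100),
                                                100))
        assert draws.mean() == pytest.approx(truth, abs=3 * mc_se)


class TestPriorOnlySampling:
    def test_pc_prec_sigma_tail(self, grid4):
        # likelihood disabled: tau_v marginal must be its pc_prec prior
        o = np.ones((grid4.n, 1))
        e = np.ones((grid4.n, 1))
        spec = ModelSpec(spatial="iid", temporal_structured="none",
                         temporal_iid="none", interaction="none",
                         priors={"tau_v": PriorSpec("pc_prec", (1.0, 0.01))})
        fit = fit_mcmc(o, e, spec, grid4, chains=2, iterations=12_000,
                       burn_in=2000, thin=2, seed=5, likelihood_scale=0.0)
        sigma = 1 / np.sqrt(fit.pooled("tau_v"))
        p_hat = float((sigma > 1.0).mean())
        ess = max(fit.ess["tau_v"], 50)
        se = np.sqrt(0.01 * 0.99 / ess)
        assert p_hat == pytest.approx(0.01, abs=max(3 * se, 0.01))


class TestEvaluation:
    @pytest.fixture()
    def toy_fit(self, grid4):
        o = np.full((grid4.n, 2), 3.0)
        e = np.full((grid4.n, 2), 2.5)
        spec = intercept_spec()
        return fit_mcmc(o, e, spec, chains=2, iterations=1200, burn_in=200,
                        thin=2, seed=3)

    def test_degenerate_posterior_gives_zero_penalties(self, toy_fit):
        fit = toy_fit
        fit.draws["eta"] = np.zeros_like(fit.draws["eta"])
        d, p_d = dic(fit)
        w, p_w = waic(fit)
        assert p_d == pytest.approx(0.0, abs=1e-8)
        assert p_w == pytest.approx(0.0, abs=1e-8)
        dev = -2 * poisson_loglik(fit.O, fit.E, np.zeros_like(fit.O))
        assert d == pytest.approx(dev)

    def test_pd_nonnegative(self, toy_fit):
        _, p_d = dic(toy_fit)
        assert p_d >= 0

    def test_shifting_eta_changes_dic_deterministically(self, toy_fit):
        fit = toy_fit
        d0, _ = dic(fit)
        c = 0.3
        eta = fit.pooled("eta")
        fit.draws["eta"] = fit.draws["eta"] + c
        d1, _ = dic(fit)

        # DIC = 2 mean_s D(eta_s) - D(mean eta); both terms shift by the
        # closed-form Poisson deviance change for a constant offset
        def dev_change(e):
            return -2 * float((fit.O * c
                               - fit.E * (np.exp(e + c) - np.exp(e))).sum())

        delta = 2 * np.mean([dev_change(e) for e in eta]) \
            - dev_change(eta.mean(axis=0))
        assert d1 - d0 == pytest.approx(delta, rel=1e-9)

    def test_waic_close_to_dic_on_well_behaved_fit(self, toy_fit):
        d, _ = dic(toy_fit)
        w, _ = waic(toy_fit)
        assert abs(d - w) < 10

    def test_single_observation_waic_analytic(self):
        o = np.array([[5.0]])
        e = np.array([[4.0]])
        fit = fit_mcmc(o, e, intercept_spec(), chains=2, iterations=4000,
                       burn_in=1000, thin=2, seed=9)
        ll = np.array([float(sps.poisson.logpmf(5, 4 * np.exp(a)))
                       for a in fit.pooled("alpha")])
        lppd = special.logsumexp(ll) - np.log(ll.size)
        p_w = ll.var(ddof=1)
        w, _ = waic(fit)
        assert w == pytest.approx(-2 * (lppd - p_w), rel=1e-10)

    def test_pit_in_unit_interval_and_deterministic(self, toy_fit):
        u1 = pit(toy_fit, seed=4)
        u2 = pit(toy_fit, seed=4)
        assert np.array_equal(u1, u2)
        assert (u1 >= 0).all() and (u1 <= 1).all()
        counts, edges = pit_histogram(toy_fit, seed=4)
        assert counts.sum() == toy_fit.O.size
        assert len(counts) == 10

    def test_dic_needs_draws(self, toy_fit):
        fit = toy_fit
        fit.draws["eta"] = fit.draws["eta"][:1, :1]
        with pytest.raises(ValueError):
            dic(fit)


class TestConvergenceReporting:
    def test_rhat_reported_for_every_hyperparameter(self, grid4):
        o = np.ones((grid4.n, 2)) * 3
        e = np.ones((grid4.n, 2)) * 3
        spec = ModelSpec(spatial="bym", temporal_structured="none",
                         temporal_iid="none", interaction="none")
        fit = fit_mcmc(o, e, spec, grid4, chains=2, iterations=800,
                       burn_in=300, thin=2, seed=6)
        for name in fit.scalar_names():
            assert name in fit.rhat
        assert {"alpha", "tau_u", "tau_v"} <= set(fit.rhat)

    def test_seed_required(self, grid4):
        with pytest.raises(ValueError, match="seed"):
            fit_mcmc(np.ones((grid4.n, 2)), np.ones((grid4.n, 2)),
                     ModelSpec(spatial="bym", temporal_structured="none",
                               temporal_iid="none", interaction="none"),
                     grid4)
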