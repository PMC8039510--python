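import warnings

import numpy as np
import pytest

from popmm.em_engine import (
    FitSettings,
    NonConvergenceWarning,
    conditional_posterior,
    conditional_std_residuals,
    em_fit,
    individual_loglik,
    lrt,
    paired_minus2LL,
    standard_errors,
    total_minus2LL,
)
from popmm.minimal_model import (InsulinForcing, MMParams, SubjectData,
                                 TestType, simulate_glucose)
from popmm.population_model import (PopulationParams,
                                    reference_base_population,
                                    typical_values)


def _self_consistent_subject(params, sigma=0.0, seed=0, n_obs=12):
    """Subject whose observations are the model's own predictions."""
    forcing = InsulinForcing(np.array([0., 4., 10., 20., 40., 80., 180.]),
                             np.array([40., 350., 200., 120., 70., 45., 40.]),
                             40.0)
    t = np.array([5., 8., 12., 16., 22., 30., 40., 60., 90., 120., 150., 180.])
    t = t[:n_obs]
    pred = simulate_glucose(params, 124.89, 5.0, 40.0, forcing, t)
    rng = np.random.default_rng(seed)
    obs = pred * (1 + sigma * rng.standard_normal(t.size)) if sigma else pred
    return SubjectData("self", TestType.IVGTT, 124.89, t, obs, forcing,
                       5.0, 40.0)


class TestIndividualLoglik:
    def test_zero_residuals_closed_form(self, base_params):
        s = _self_consistent_subject(base_params)
        sigma = 0.08
        ll = individual_loglik(s, np.log(base_params.as_array()), sigma)
        yhat = simulate_glucose(base_params, s.dose, s.Gbasal, s.Ibasal,
                                s.forcing, s.obs_times)
        expected = np.sum(-np.log(sigma * yhat * np.sqrt(2 * np.pi)))
        assert ll == pytest.approx(expected, rel=1e-9)

    def test_doubling_sigma_costs_n_log2(self, base_params):
        s = _self_consistent_subject(base_params)
        l1 = individual_loglik(s, np.log(base_params.as_array()), 0.05)
        l2 = individual_loglik(s, np.log(base_params.as_array()), 0.10)
        assert l1 - l2 == pytest.approx(s.obs_times.size * np.log(2), rel=1e-9)

    def test_matches_term_by_term_density(self, base_params):
        from scipy.stats import norm
        s = _self_consistent_subject(base_params, sigma=0.07, seed=3)
        theta = base_params.as_array() * [1.1, 0.9, 1.2, 0.95]
        sigma = 0.07
        ll = individual_loglik(s, np.log(theta), sigma)
        yhat = simulate_glucose(MMParams.from_array(theta), s.dose, s.Gbasal,
                                s.Ibasal, s.forcing, s.obs_times)
        expected = norm.logpdf(s.obs_glucose, loc=yhat,
                               scale=sigma * yhat).sum()
        assert ll == pytest.approx(expected, rel=1e-9)


class TestConditionalPosterior:
    def test_tight_prior_pins_to_population_mean(self, base_params):
        s = _self_consistent_subject(base_params, sigma=0.07, seed=1)
        mu = np.log(base_params.as_array()) + 0.3
        pop = PopulationParams(mu, 1e-6 * np.eye(4), sigma_prop=0.07)
        cp = conditional_posterior(s, pop, FitSettings(seed=2))
        np.testing.assert_allclose(cp.mean, mu, atol=0.02)

    def test_rich_noiseless_data_recovers_truth(self, base_params):
        s = _self_consistent_subject(base_params, sigma=1e-4, seed=2)
        pop = PopulationParams(np.log(base_params.as_array()) + 0.2,
                               0.25 * np.eye(4), sigma_prop=1e-4)
        cp = conditional_posterior(s, pop, FitSettings(
            n_importance_samples=500, seed=4))
        np.testing.assert_allclose(cp.mean, np.log(base_params.as_array()),
                                   atol=0.01)
        assert cp.weights.sum() == pytest.approx(1.0)
        assert 0 < cp.ess <= 500


class TestLRT:
    def test_zero_statistic(self):
        assert lrt(100.0, 100.0, 1) == pytest.approx(1.0)

    def test_chi2_critical_value(self):
        assert lrt(103.841, 100.0, 1) == pytest.approx(0.050, abs=1e-3)

    def test_negative_difference_rejected(self):
        with pytest.raises(ValueError):
            lrt(100.0, 110.0, 1)
        with pytest.raises(ValueError):
            lrt(100.0, 100.0, 0)


@pytest.fixture(scope="module")
def toy():
    """3 sparse subjects with a prior wide in (GEZI, SI) only, so that
    tensor Gauss-Hermite quadrature of the marginal is well resolved."""
    params = MMParams(GEZI=0.02, SI=5e-5, p2=0.04, V=12.0)
    subs = [_self_consistent_subject(params, sigma=0.15, seed=s, n_obs=6)
            for s in range(3)]
    pop = PopulationParams(np.log(params.as_array()),
                           np.diag([0.04, 0.09, 1e-6, 1e-6]),
                           sigma_prop=0.15)
    return subs, pop


class TestMarginalLikelihood:
    def test_matches_gauss_hermite_quadrature(self, toy):
        subs, pop = toy
        st = FitSettings(n_ll_samples=4000, seed=5)
        m2, se = total_minus2LL(subs, pop, st)
        # independent oracle: tensor-product Gauss-Hermite over the
        # diagonal-normal prior (15 nodes on the wide axes, 3 on the tight)
        n_wide, w_wide = np.polynomial.hermite_e.hermegauss(15)
        n_tight, w_tight = np.polynomial.hermite_e.hermegauss(3)
        sd = np.sqrt(np.diag(pop.Sigma_logtheta))
        total = 0.0
        for s in subs:
            acc = 0.0
            for i, xi in enumerate(n_wide):
                for j, xj in enumerate(n_wide):
                    for k, xk in enumerate(n_tight):
                        for l, xl in enumerate(n_tight):
                            eta = pop.mu_logtheta + sd * np.array(
                                [xi, xj, xk, xl])
                            ll = individual_loglik(s, eta, pop.sigma_prop)
                            w = w_wide[i] * w_wide[j] * w_tight[k] * w_tight[l]
                            acc += w * np.exp(ll)
            total += np.log(acc / (2 * np.pi) ** 2)
        assert m2 == pytest.approx(-2.0 * total, abs=0.5)

    def test_variance_shrinks_with_more_samples(self, toy):
        subs, pop = toy
        small = total_minus2LL(subs, pop, FitSettings(n_ll_samples=200, seed=5))
        large = total_minus2LL(subs, pop, FitSettings(n_ll_samples=3200, seed=5))
        assert large[1] < small[1]

    def test_paired_equals_direct_for_identical_pops(self, toy):
        subs, pop = toy
        st = FitSettings(n_ll_samples=1000, seed=5)
        m2r, m2f = paired_minus2LL(subs, pop, pop, st)
        assert m2r == pytest.approx(m2f, abs=1e-9)
        direct, _ = total_minus2LL(subs, pop, st)
        assert m2f == pytest.approx(direct, abs=1e-6)


class TestEMFit:
    def test_degenerate_noise_recovery(self, degenerate_fit):
        tv = typical_values(degenerate_fit.pop)
        for name, true in (("GEZI", 0.0178), ("SI", 3.59e-5),
                           ("p2", 0.0425), ("V", 12.4)):
            assert tv[name] == pytest.approx(true, rel=0.01), name

    def test_requires_ten_subjects(self, small_trial):
        with pytest.raises(ValueError):
            em_fit(small_trial.subjects[:5])

    def test_seeded_determinism(self, degenerate_trial):
        st = FitSettings(n_importance_samples=50, max_iterations=12,
                         min_iterations=12, seed=21)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", NonConvergenceWarning)
            a = em_fit(degenerate_trial.subjects, settings=st)
            b = em_fit(degenerate_trial.subjects, settings=st)
        np.testing.assert_array_equal(a.pop.mu_logtheta, b.pop.mu_logtheta)
        np.testing.assert_array_equal(a.pop.Sigma_logtheta,
                                      b.pop.Sigma_logtheta)
        assert a.minus2LL == b.minus2LL

    def test_residuals_near_zero_for_degenerate_fit(self, degenerate_fit,
                                                    degenerate_trial):
        res = conditional_std_residuals(degenerate_fit,
                                        degenerate_trial.subjects)
        # residual SD scale is sigma~1e-3, standardized residuals O(1)
        assert res.cond_std_residual.abs().mean() < 3.0
        assert set(res.columns) >= {"subject_id", "time_min",
                                    "cond_std_residual", "pop_std_residual"}

    def test_standard_errors_bootstrap_path(self, degenerate_fit,
                                            degenerate_trial):
        st = degenerate_fit.settings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = standard_errors(degenerate_fit, degenerate_trial.subjects,
                                  st, method="bootstrap")
        assert set(out) >= {"TV_GEZI", "TV_V", "sigma_prop"}
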