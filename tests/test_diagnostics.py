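"""CV convergence series, Savage-Dickey Bayes factors, bridge prior mass."""

import numpy as np
import pytest
from scipy.stats import norm

from glidetree.diagnostics import (DiagnosticsError,
                                   bridge_difference_prior_at_zero,
                                   cv_series_mcmc, cv_series_vi,
                                   savage_dickey_bf, summarize_posterior)


class TestCVSeriesVI:
    def test_constant_mean_and_variance(self):
        s = cv_series_vi(np.full(10, 2.0), np.full(10, 1.0))
        assert np.allclose(s.cv, 0.5, atol=1e-15)
        assert np.allclose(s.squared_deviation, 0.0, atol=1e-15)

    def test_alternating_means_zero_variance(self):
        means = np.tile([1.0, 3.0], 50)
        s = cv_series_vi(means, np.zeros(100))
        assert np.allclose(s.cv, 0.0, atol=1e-15)

    def test_matches_cumulative_average_oracle(self, rng):
        means = rng.uniform(1, 3, size=200)
        variances = rng.uniform(0.1, 2, size=200)
        s = cv_series_vi(means, variances)
        for i in (0, 7, 99, 199):
            mu_bar = means[:i + 1].mean()
            var_bar = variances[:i + 1].mean()
            assert s.cv[i] == pytest.approx(np.sqrt(var_bar) / mu_bar, abs=1e-12)
        assert s.squared_deviation[-1] == 0.0

    def test_zero_running_mean_rejected(self):
        with pytest.raises(DiagnosticsError):
            cv_series_vi(np.zeros(3), np.ones(3))

    def test_converging_sequence_deviations_shrink(self, rng):
        # a run settling toward (mu, var) = (2, 0.5): early squared
        # deviations from the final CV exceed late ones on average
        j = np.arange(1, 201)
        means = 2.0 + 3.0 / j + rng.normal(scale=0.01, size=200)
        variances = 0.5 + 2.0 / j
        s = cv_series_vi(means, variances)
        assert s.squared_deviation[:100].mean() > s.squared_deviation[100:].mean()
        assert s.squared_deviation[-1] == 0.0


class TestCVSeriesMCMC:
    def test_iid_normal_matches_analytic_cv(self, rng):
        draws = rng.normal(10.0, 1.0, size=100_000)
        s = cv_series_mcmc(draws, checkpoint_every=1000)
        n = len(draws)
        se = 0.1 * np.sqrt(1 / (2 * n) + 0.01 / n)
        assert abs(s.final_cv - 0.1) < 3 * se

    def test_constant_samples(self):
        s = cv_series_mcmc(np.full(50, 3.0), checkpoint_every=10)
        assert np.allclose(s.cv, 0.0)

    def test_two_samples_hand_arithmetic(self):
        s = cv_series_mcmc(np.array([1.0, 3.0]), checkpoint_every=2)
        assert s.cv[-1] == pytest.approx(np.sqrt(2) / 2, abs=1e-12)


class TestSavageDickey:
    def test_identical_densities_give_unit_bf(self):
        r = savage_dickey_bf(norm.pdf(0), posterior=(0.0, 1.0))
        assert r.log_bf10 == pytest.approx(0.0, abs=1e-12)

    def test_shifted_posterior_standard_normal_ratio(self):
        r = savage_dickey_bf(norm.pdf(0), posterior=(1.0, 1.0))
        assert np.exp(r.log_bf10) == pytest.approx(np.exp(0.5), rel=1e-10)

    def test_kde_agrees_with_gaussian_marginal(self, rng):
        draws = rng.normal(0.8, 1.3, size=100_000)
        exact = savage_dickey_bf(norm.pdf(0), posterior=(0.8, 1.3))
        kde = savage_dickey_bf(norm.pdf(0), samples=draws, method="kde")
        assert abs(kde.log_bf10 - exact.log_bf10) < np.log(1.05)

    def test_analytic_conjugate_bayes_factor(self):
        """On a normal-normal model the Savage-Dickey BF from the exact
        posterior equals the likelihood-ratio form of the BF."""
        prior_sd, obs_sd = 1.5, 1.0
        obs = np.array([0.7, 1.1, 0.2])
        n = len(obs)
        post_prec = 1 / prior_sd ** 2 + n / obs_sd ** 2
        post_sd = 1 / np.sqrt(post_prec)
        post_mean = (obs.sum() / obs_sd ** 2) / post_prec
        r = savage_dickey_bf(norm.pdf(0, 0, prior_sd),
                             posterior=(post_mean, post_sd))
        # independent route: BF10 = m1(y)/m0(y) with m0 the point-null
        from scipy.stats import multivariate_normal
        cov1 = obs_sd ** 2 * np.eye(n) + prior_sd ** 2 * np.ones((n, n))
        m1 = multivariate_normal.logpdf(obs, mean=np.zeros(n), cov=cov1)
        m0 = norm.logpdf(obs, 0, obs_sd).sum()
        assert r.log_bf10 == pytest.approx(m1 - m0, abs=1e-10)

    def test_input_validation(self):
        with pytest.raises(DiagnosticsError):
            savage_dickey_bf(0.0, posterior=(0, 1))
        with pytest.raises(DiagnosticsError):
            savage_dickey_bf(0.4, posterior=(0, -1))
        with pytest.raises(DiagnosticsError):
            savage_dickey_bf(0.4, samples=np.zeros(5), method="kde")


class TestBridgePriorAtZero:
    def test_study_hyperparameters_closed_forms(self):
        r = bridge_difference_prior_at_zero(0.25, 1.0, 2.0, n_mc=200_000,
                                            rng=np.random.default_rng(1))
        assert r.single_closed_form == pytest.approx(8.0, abs=1e-12)
        assert r.difference_closed_form == pytest.approx(0.5, abs=1e-12)
        assert abs(r.single_mc - 8.0) < 3 * r.single_mc_se
        assert abs(r.difference_mc - 0.5) < 3 * r.difference_mc_se

    @pytest.mark.parametrize("alpha,tau", [(0.25, 1.0), (0.25, 0.4), (0.5, 2.0)])
    def test_difference_density_by_convolution_quadrature(self, alpha, tau):
        """Independent oracle for the 2^(-1/alpha) factor: the density of
        eps_a - eps_b at zero equals int p(u)^2 du (symmetry), computed by
        quadrature of the bridge density."""
        from scipy.integrate import quad
        from scipy.special import gammaln
        norm_c = alpha / (2 * tau * np.exp(gammaln(1 / alpha)))
        oracle = quad(lambda u: (norm_c * np.exp(-abs(u / tau) ** alpha)) ** 2,
                      -np.inf, np.inf, limit=800)[0]
        closed = 2.0 ** (-1.0 / alpha) * norm_c
        assert closed == pytest.approx(oracle, rel=1e-4)  # quadrature-limited

    def test_gaussian_exponent_reduces_to_normal_convolution(self):
        """alpha = 2: each effect is N(0, tau^2/2); the difference is
        N(0, tau^2), so its density at zero is E[1/(tau sqrt(2 pi))]."""
        delta, theta_s = 3.0, 1.5
        rng = np.random.default_rng(3)
        r = bridge_difference_prior_at_zero(2.0, delta, theta_s, n_mc=200_000,
                                            rng=rng)
        nu = np.random.default_rng(4).gamma(delta, theta_s, size=400_000)
        tau = nu ** (-0.5)
        oracle = np.mean(1.0 / (tau * np.sqrt(2 * np.pi)))
        assert r.difference_closed_form == pytest.approx(oracle, rel=0.01)


class TestSummaries:
    def test_gaussian_closed_form_quantiles(self):
        s = summarize_posterior(mean=0.0, sd=1.0)
        assert s["median"] == pytest.approx(0.0, abs=1e-12)
        assert s["lo95"] == pytest.approx(-1.959964, abs=1e-5)
        assert s["hi95"] == pytest.approx(1.959964, abs=1e-5)

    def test_log_transform_median_is_lognormal_median(self):
        s = summarize_posterior(mean=0.0, sd=1.0, transform=np.exp)
        assert s["median"] == pytest.approx(1.0, abs=1e-10)

    def test_empirical_quantiles_match_analytic(self, rng):
        s = summarize_posterior(samples=rng.normal(size=100_000))
        assert abs(s["median"]) < 0.02
        assert abs(s["lo95"] + 1.96) < 0.03
        assert abs(s["hi95"] - 1.96) < 0.03
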