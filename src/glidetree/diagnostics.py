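"""Convergence and hypothesis-testing diagnostics.

* Coefficient-of-variation (CV) series: a scale-free convergence summary
  comparable across MCMC and VI.  For VI the per-checkpoint variational
  means and variances are smoothed by running averages; for MCMC the CV at
  checkpoint i uses all draws up to i.  Plots of (CV(t_i) - CV(t_M))^2
  against time show how fast each algorithm settles.
* Savage-Dickey Bayes factors for point hypotheses nested in a continuous
  model: BF10 = prior density at the point / posterior density at the
  point.  Positive log BF10 favors the unrestricted (nonreversible) model.
* The marginal prior density at zero of Bayesian-bridge random effects
  (and of differences of two effects), in closed form and by Monte Carlo.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import gaussian_kde

_SQRT_2PI = float(np.sqrt(2.0 * np.pi))


class DiagnosticsError(ValueError):
    pass


@dataclass
class CVSeries:
    checkpoints: np.ndarray
    cv: np.ndarray
    squared_deviation: np.ndarray  # (CV(t_i) - CV(t_M))^2

    @property
    def final_cv(self) -> float:
        return float(self.cv[-1])


def cv_series_vi(means, variances, checkpoints=None) -> CVSeries:
    """CV(t_i) = sqrt(mean of variances up to i) / (mean of means up to i).

    ``means``/``variances`` are the per-checkpoint variational marginal
    mean and variance of one parameter.
    """
    means = np.asarray(means, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if means.shape != variances.shape or means.ndim != 1 or len(means) == 0:
        raise DiagnosticsError("means and variances must be equal-length 1-d")
    idx = np.arange(1, len(means) + 1)
    mu_bar = np.cumsum(means) / idx
    var_bar = np.cumsum(variances) / idx
    if np.any(mu_bar == 0):
        raise DiagnosticsError("running mean is zero; CV undefined")
    cv = np.sqrt(var_bar) / mu_bar
    if checkpoints is None:
        checkpoints = idx
    return CVSeries(np.asarray(checkpoints), cv, (cv - cv[-1]) ** 2)


def cv_series_mcmc(samples, checkpoint_every=1000) -> CVSeries:
    """CV at checkpoint i from draws 1..i (sample sd, denominator n-1)."""
    samples = np.asarray(samples, dtype=float)
    points = np.arange(checkpoint_every, len(samples) + 1, checkpoint_every)
    if len(points) == 0 or points[-1] != len(samples):
        points = np.append(points, len(samples))
    cv = np.empty(len(points))
    for j, i in enumerate(points):
        if i < 2:
            raise DiagnosticsError("need at least two samples per checkpoint")
        chunk = samples[:i]
        mean = chunk.mean()
        if mean == 0:
            raise DiagnosticsError("sample mean is zero; CV undefined")
        cv[j] = chunk.std(ddof=1) / mean
    return CVSeries(points, cv, (cv - cv[-1]) ** 2)


@dataclass
class BayesFactorResult:
    log_bf10: float
    prior_at_zero: float
    posterior_at_zero: float
    method: str


def savage_dickey_bf(prior_at_zero: float, posterior=None, samples=None,
                     method: str = "gaussian_marginal") -> BayesFactorResult:
    """Savage-Dickey Bayes factor for the point null at zero.

    ``posterior`` is a (mean, sd) pair for the Gaussian-marginal method
    (exact under a mean-field fit); ``samples`` feeds the KDE method.
    """
    if prior_at_zero <= 0:
        raise DiagnosticsError("prior density at zero must be positive")
    if method == "gaussian_marginal":
        if posterior is None:
            raise DiagnosticsError("gaussian_marginal needs (mean, sd)")
        m, s = posterior
        if s <= 0:
            raise DiagnosticsError("posterior sd must be positive")
        post0 = float(np.exp(-0.5 * (m / s) ** 2) / (s * _SQRT_2PI))
    elif method == "kde":
        if samples is None or len(samples) < 10:
            raise DiagnosticsError("kde needs at least 10 samples")
        post0 = float(gaussian_kde(np.asarray(samples, dtype=float))(0.0)[0])
    else:
        raise DiagnosticsError(f"unknown method {method!r}")
    return BayesFactorResult(float(np.log(prior_at_zero) - np.log(post0)),
                             prior_at_zero, post0, method)


@dataclass
class BridgePriorAtZero:
    single_closed_form: float
    single_mc: float
    single_mc_se: float
    difference_closed_form: float
    difference_mc: float
    difference_mc_se: float


def bridge_difference_prior_at_zero(alpha: float, delta: float, theta_s: float,
                                    n_mc: int = 100_000, rng=None) -> BridgePriorAtZero:
    """Marginal prior density at zero of one bridge effect and of the
    difference of two, with tau^(-alpha) ~ Gamma(shape=delta, scale=theta_s).

    Closed forms: E[density of eps at 0] = alpha theta^(1/alpha)
    Gamma(delta + 1/alpha) / (2 Gamma(1/alpha) Gamma(delta)); the density
    of eps_a - eps_b at zero is 2^(-1/alpha) times that.  Monte Carlo
    averages the conditional-on-tau densities over tau draws.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    inv_a = 1.0 / alpha
    log_single = (np.log(alpha) + inv_a * np.log(theta_s)
                  + gammaln(delta + inv_a) - np.log(2.0)
                  - gammaln(inv_a) - gammaln(delta))
    single_cf = float(np.exp(log_single))
    diff_cf = float(2.0 ** (-inv_a) * single_cf)

    nu = rng.gamma(shape=delta, scale=theta_s, size=n_mc)
    inv_tau = nu ** inv_a  # tau = nu^(-1/alpha)
    cond = alpha / (2.0 * np.exp(gammaln(inv_a))) * inv_tau
    single_mc = float(cond.mean())
    single_se = float(cond.std(ddof=1) / np.sqrt(n_mc))
    cond_diff = 2.0 ** (-inv_a) * cond
    diff_mc = float(cond_diff.mean())
    diff_se = float(cond_diff.std(ddof=1) / np.sqrt(n_mc))
    return BridgePriorAtZero(single_cf, single_mc, single_se,
                             diff_cf, diff_mc, diff_se)


def summarize_posterior(samples=None, mean=None, sd=None,
                        transform=None) -> dict:
    """Median, mean, sd and central 50%/95% intervals.

    Either empirical (``samples``) or closed-form Gaussian quantiles
    (``mean``/``sd`` on the unconstrained scale), optionally mapped through
    a monotone ``transform`` callable.
    """
    probs = {"median": 0.5, "lo95": 0.025, "hi95": 0.975,
             "lo50": 0.25, "hi50": 0.75}
    if samples is not None:
        s = np.asarray(samples, dtype=float)
        if len(s) < 10:
            raise DiagnosticsError("need at least 10 samples")
        out = {k: float(np.quantile(s, p)) for k, p in probs.items()}
        out["mean"] = float(s.mean())
        out["sd"] = float(s.std(ddof=1))
        return out
    if mean is None or sd is None:
        raise DiagnosticsError("supply samples or (mean, sd)")
    from scipy.stats import norm
    q = {k: mean + sd * norm.ppf(p) for k, p in probs.items()}
    if transform is not None:
        q = {k: float(transform(v)) for k, v in q.items()}
        draws = transform(mean + sd * norm.ppf(np.linspace(5e-4, 1 - 5e-4, 2000)))
        return {**q, "mean": float(np.mean(draws)), "sd": float(np.std(draws))}
    return {**{k: float(v) for k, v in q.items()},
            "mean": float(mean), "sd": float(sd)}
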