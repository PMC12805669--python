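"""Small closed-form target posteriors for calibration and testing.

The conjugate normal-normal model has an analytic posterior and evidence,
which makes it the canonical check for every inference engine: VI should
recover the posterior mean/sd, MAP the mode, the ELBO at the optimum the
evidence, and SNIS the forward KL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .posterior import JointPosterior, ParameterBlock
from .priors import normal_logpdf
from .transforms import Identity


@dataclass
class ConjugateNormal:
    """y_i ~ N(theta, obs_sd), theta ~ N(prior_mean, prior_sd)."""

    prior_mean: float
    prior_sd: float
    obs: np.ndarray
    obs_sd: float

    @property
    def posterior_precision(self) -> float:
        return 1.0 / self.prior_sd ** 2 + len(self.obs) / self.obs_sd ** 2

    @property
    def posterior_sd(self) -> float:
        return float(1.0 / np.sqrt(self.posterior_precision))

    @property
    def posterior_mean(self) -> float:
        num = (self.prior_mean / self.prior_sd ** 2
               + self.obs.sum() / self.obs_sd ** 2)
        return float(num / self.posterior_precision)

    @property
    def log_evidence(self) -> float:
        """Marginal likelihood of the data (all-Gaussian, closed form)."""
        from scipy.stats import multivariate_normal
        n = len(self.obs)
        cov = self.obs_sd ** 2 * np.eye(n) + self.prior_sd ** 2 * np.ones((n, n))
        return float(multivariate_normal.logpdf(self.obs, mean=np.full(n, self.prior_mean),
                                                cov=cov))

    def model(self) -> JointPosterior:
        blocks = [ParameterBlock(
            "theta", Identity(1),
            prior=lambda x: normal_logpdf(x[0], self.prior_mean, self.prior_sd))]

        def lik(values):
            th = values["theta"][0]
            total = 0.0
            for y in self.obs:
                total = ad.add(total, normal_logpdf(th, y, self.obs_sd))
            return total

        return JointPosterior(blocks, [("likelihood", lik)])


def standard_normal_model(dim: int) -> JointPosterior:
    """Independent standard normal target in `dim` dimensions."""
    blocks = [ParameterBlock("z", Identity(dim), prior=lambda x: normal_logpdf(x))]
    return JointPosterior(blocks, [])


def gaussian_model(mean, sd) -> JointPosterior:
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    sd = np.broadcast_to(np.asarray(sd, dtype=float), mean.shape)

    def prior(x):
        total = 0.0
        for i in range(len(mean)):
            total = ad.add(total, normal_logpdf(x[i], mean[i], sd[i]))
        return total

    return JointPosterior([ParameterBlock("z", Identity(len(mean)), prior=prior)], [])


def mixture_model(means, sds, weights) -> JointPosterior:
    """1-d Gaussian mixture target (used to exhibit mode-seeking vs
    mass-covering behavior of the two VI objectives)."""
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    weights = np.asarray(weights, dtype=float)
    log_w = np.log(weights / weights.sum())

    def logp(values):
        z = values["z"][0]
        comps = [ad.add(log_w[c], normal_logpdf(z, means[c], sds[c]))
                 for c in range(len(means))]
        return ad.logsumexp(ad.stack(comps))

    return JointPosterior([ParameterBlock("z", Identity(1))], [("mixture", logp)])
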