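"""Log prior densities (autodiff-compatible).

Includes the Bayesian bridge shrinkage prior used for substitution-rate
random effects: p(eps | tau, alpha) = alpha / (2 tau Gamma(1/alpha)) *
exp(-|eps/tau|^alpha).  Small alpha (0.25 here) gives a sharp spike at
zero with heavy tails, shrinking most effects while letting a few escape.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

from . import autodiff as ad

LOG_2PI = float(np.log(2.0 * np.pi))


def normal_logpdf(x, mean=0.0, sd=1.0):
    z = ad.div(ad.sub(x, mean), sd)
    n = np.size(ad.value_of(x))
    return ad.sub(ad.mul(-0.5, ad.asum(ad.mul(z, z))),
                  n * (0.5 * LOG_2PI + np.log(sd)))


def gamma_logpdf(x, shape: float, rate: float):
    """Gamma density with shape/rate parameterization."""
    if shape <= 0 or rate <= 0:
        raise ValueError("gamma shape and rate must be positive")
    lx = ad.log(x)
    return ad.add(shape * np.log(rate) - gammaln(shape),
                  ad.sub(ad.mul(shape - 1.0, lx), ad.mul(rate, x)))


def lognormal_logpdf(x, mean: float, sd: float):
    lx = ad.log(x)
    z = ad.div(ad.sub(lx, mean), sd)
    return ad.sub(ad.mul(-0.5, ad.mul(z, z)), ad.add(lx, 0.5 * LOG_2PI + np.log(sd)))


def dirichlet_logpdf(x, concentration=1.0):
    """Symmetric Dirichlet; concentration 1 is the flat simplex prior."""
    k = np.size(ad.value_of(x))
    const = gammaln(k * concentration) - k * gammaln(concentration)
    if concentration == 1.0:
        return const
    return ad.add(const, ad.mul(concentration - 1.0, ad.asum(ad.log(x))))


def bridge_log_density(eps, tau, alpha: float):
    """Bayesian bridge log density, summed over the effects vector.

    Normalizer: integral of exp(-|x/tau|^alpha) over the real line is
    2 tau Gamma(1 + 1/alpha) = 2 tau Gamma(1/alpha) / alpha.
    """
    if not 0 < alpha <= 2:
        raise ValueError("bridge exponent must be in (0, 2]")
    if float(ad.value_of(tau)) <= 0:
        raise ValueError("bridge scale must be positive")
    n = np.size(ad.value_of(eps))
    log_norm = np.log(alpha) - np.log(2.0) - gammaln(1.0 / alpha)
    kernel = ad.asum(ad.power(ad.absolute(ad.div(eps, tau)), alpha))
    return ad.sub(ad.sub(n * log_norm, ad.mul(float(n), ad.log(tau))), kernel)


def bridge_density_at_zero(tau, alpha: float) -> float:
    """Density of a single bridge effect evaluated at zero."""
    return float(np.exp(np.log(alpha) - np.log(2.0) - gammaln(1.0 / alpha))
                 / ad.value_of(tau))
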