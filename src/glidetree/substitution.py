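"""Nucleotide substitution models, discrete site-rate models, strict clock.

Rate matrices are normalized to one expected substitution per unit time
(-sum_i pi_i Q_ii = 1) so branch durations are in expected-substitution
units once multiplied by the clock rate.  The HKY random-effects variant
multiplies each off-diagonal entry by exp(eps_ij) (one effect per ordered
pair), breaking reversibility; the matrix is re-normalized afterwards so
the effects change relative, not absolute, rates and the clock rate stays
identifiable.

All matrix builders are written against the autodiff dispatch layer, so the
same code produces plain numpy matrices or differentiable graph nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm as _expm
from scipy.stats import gamma as _gamma_dist

from . import autodiff as ad

STATE_ORDER = "ACGT"

_I4 = np.eye(4)
_OFF = 1.0 - _I4
# transitions: A<->G (0,2), C<->T (1,3)
_TRANSITIONS = np.zeros((4, 4))
_TRANSITIONS[0, 2] = _TRANSITIONS[2, 0] = 1.0
_TRANSITIONS[1, 3] = _TRANSITIONS[3, 1] = 1.0

# unordered pair masks in the canonical order AC, AG, AT, CG, CT, GT
GTR_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
_PAIR_MASKS = []
for (i, j) in GTR_PAIRS:
    m = np.zeros((4, 4))
    m[i, j] = m[j, i] = 1.0
    _PAIR_MASKS.append(m)

# ordered pairs for random effects, row-major excluding the diagonal
RE_PAIRS = [(i, j) for i in range(4) for j in range(4) if i != j]
_RE_MASKS = []
for (i, j) in RE_PAIRS:
    m = np.zeros((4, 4))
    m[i, j] = 1.0
    _RE_MASKS.append(m)


def re_pair_label(idx: int) -> str:
    i, j = RE_PAIRS[idx]
    return f"{STATE_ORDER[i]}>{STATE_ORDER[j]}"


def _check_simplex(freqs):
    f = ad.value_of(freqs)
    if np.any(f <= 0) or abs(f.sum() - 1.0) > 1e-8:
        raise ValueError("frequencies must be a positive simplex")


def build_rate_matrix(name, frequencies, kappa=None, rates=None, random_effects=None):
    """Assemble a normalized 4x4 rate matrix.

    Parameters may be floats/arrays or autodiff tensors.  ``name`` is one
    of ``jc69``, ``hky``, ``gtr``; ``random_effects`` (length-12, ordered
    per :data:`RE_PAIRS`) may be combined with any base model.
    """
    name = name.lower()
    if name == "jc69":
        base = np.ones((4, 4))
        frequencies = np.full(4, 0.25)
    elif name == "hky":
        if kappa is None:
            raise ValueError("hky requires kappa")
        base = ad.add(1.0, ad.mul(ad.sub(kappa, 1.0), _TRANSITIONS))
    elif name == "gtr":
        if rates is None:
            raise ValueError("gtr requires 6 exchange rates")
        base = 0.0
        for k in range(6):
            base = ad.add(base, ad.mul(rates[k], _PAIR_MASKS[k]))
    else:
        raise ValueError(f"unknown substitution model {name!r}")
    _check_simplex(frequencies)

    q = ad.mul(base, frequencies)  # column j scaled by pi_j
    if random_effects is not None:
        eps = 0.0
        for k in range(12):
            eps = ad.add(eps, ad.mul(random_effects[k], _RE_MASKS[k]))
        q = ad.mul(q, ad.exp(eps))
    q = ad.mul(q, _OFF)
    row_sums = ad.asum(q, axis=1)
    q = ad.sub(q, ad.mul(ad.reshape(row_sums, (4, 1)), _I4))
    # -sum_i pi_i Q_ii with the random effects already applied, so the
    # normalization is recomputed after the effects
    rate = ad.asum(ad.mul(frequencies, row_sums))
    return ad.div(q, rate)


@dataclass
class SubstitutionModel:
    """Concrete (non-differentiable) substitution model for simulation and
    direct likelihood evaluation."""

    name: str
    frequencies: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    kappa: float | None = None
    rates: np.ndarray | None = None
    random_effects: np.ndarray | None = None

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.name.lower() == "jc69":
            self.frequencies = np.full(4, 0.25)
        if self.kappa is not None and self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.rates is not None:
            self.rates = np.asarray(self.rates, dtype=float)
            if np.any(self.rates <= 0):
                raise ValueError("GTR exchange rates must be positive")
        if self.random_effects is not None:
            self.random_effects = np.asarray(self.random_effects, dtype=float)
            if self.random_effects.shape != (12,):
                raise ValueError("random effects must have length 12")

    @property
    def reversible(self) -> bool:
        return self.random_effects is None or np.allclose(self.random_effects, 0.0)

    def rate_matrix(self) -> np.ndarray:
        return build_rate_matrix(self.name, self.frequencies, self.kappa,
                                 self.rates, self.random_effects)

    def transition_probs(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt) for t in expected-substitution units.

        Reversible models go through the symmetric eigendecomposition of
        diag(pi)^1/2 Q diag(pi)^-1/2 (stable, exact); the nonreversible
        random-effects matrix uses the dense Pade matrix exponential.
        """
        if t < 0:
            raise ValueError("t must be nonnegative")
        q = self.rate_matrix()
        if not self.reversible:
            return _expm(q * t)
        pi = self.frequencies
        sq = np.sqrt(pi)
        # S = D^{1/2} Q D^{-1/2} is symmetric under detailed balance
        sym = q * (sq[:, None] / sq[None, :])
        sym = 0.5 * (sym + sym.T)
        w, v = np.linalg.eigh(sym)
        p = (v * np.exp(w * t)) @ v.T
        p = p * (sq[None, :] / sq[:, None])
        return np.clip(p, 0.0, None)


def JC69() -> SubstitutionModel:
    return SubstitutionModel("jc69")


def HKY(kappa: float, frequencies=None) -> SubstitutionModel:
    return SubstitutionModel("hky", frequencies if frequencies is not None
                             else np.full(4, 0.25), kappa=kappa)


def GTR(rates, frequencies=None) -> SubstitutionModel:
    return SubstitutionModel("gtr", frequencies if frequencies is not None
                             else np.full(4, 0.25), rates=rates)


def HKY_RE(kappa: float, frequencies=None, random_effects=None) -> SubstitutionModel:
    eps = np.zeros(12) if random_effects is None else random_effects
    return SubstitutionModel("hky", frequencies if frequencies is not None
                             else np.full(4, 0.25), kappa=kappa, random_effects=eps)


# -- site-rate models ------------------------------------------------------

@dataclass
class SiteRateModel:
    kind: str
    shape: float | None
    rates: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        mean = float(self.rates @ self.weights)
        if abs(mean - 1.0) > 1e-12:
            raise ValueError(f"site rates must have mean 1, got {mean}")

    @property
    def n_categories(self) -> int:
        return len(self.rates)


def constant_rates() -> SiteRateModel:
    return SiteRateModel("constant", None, np.array([1.0]), np.array([1.0]))


def weibull_rates_raw(shape, K: int):
    """Median (quantile-midpoint) Weibull category rates, renormalized to
    mean exactly 1.  Autodiff-friendly: the unit-mean Weibull scale cancels
    in the renormalization, leaving only (-log(1-p))^(1/shape) terms."""
    p = (2.0 * np.arange(1, K + 1) - 1.0) / (2.0 * K)
    raw = ad.power(-np.log(1.0 - p), ad.div(1.0, shape))
    return ad.div(raw, ad.div(ad.asum(raw), float(K)))


def discrete_weibull_rates(shape: float, K: int) -> SiteRateModel:
    if shape <= 0:
        raise ValueError("Weibull shape must be positive")
    if K < 1:
        raise ValueError("need at least one category")
    if K == 1:
        return SiteRateModel("weibull", shape, np.array([1.0]), np.array([1.0]))
    rates = np.asarray(weibull_rates_raw(float(shape), K))
    return SiteRateModel("weibull", shape, rates, np.full(K, 1.0 / K))


def _gamma_quantile_rates(shape: float, K: int) -> np.ndarray:
    p = (2.0 * np.arange(1, K + 1) - 1.0) / (2.0 * K)
    raw = _gamma_dist.ppf(p, a=shape, scale=1.0 / shape)
    return raw / (raw.sum() / K)


def gamma_rates_ad(shape, K: int, fd_step: float = 1e-6):
    """Differentiable discrete-gamma rates.

    The gamma inverse CDF has no convenient closed-form derivative in its
    shape parameter, so the reverse rule uses central finite differences
    (the same device used by production AD phylogenetics codes for this
    model)."""
    if not isinstance(shape, ad.Tensor):
        return _gamma_quantile_rates(float(shape), K)
    a = float(shape.value)
    value = _gamma_quantile_rates(a, K)
    h = fd_step * max(1.0, abs(a))
    deriv = (_gamma_quantile_rates(a + h, K) - _gamma_quantile_rates(a - h, K)) / (2 * h)
    return ad.custom_primitive(value, [(shape, lambda g: float(np.dot(g, deriv)))])


def discrete_gamma_rates(shape: float, K: int) -> SiteRateModel:
    """Mean-1 discretized gamma: quantile midpoints of Gamma(shape, shape),
    renormalized so the category mean is exactly 1."""
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    if K < 1:
        raise ValueError("need at least one category")
    if K == 1:
        return SiteRateModel("gamma", shape, np.array([1.0]), np.array([1.0]))
    return SiteRateModel("gamma", shape, _gamma_quantile_rates(shape, K),
                         np.full(K, 1.0 / K))


@dataclass
class StrictClock:
    """Single substitution rate (subst/site/year) converting height
    differences to expected substitutions."""

    rate: float
    fixed: bool = False

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("clock rate must be positive")
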