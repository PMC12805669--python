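"""Simulators for coalescent time trees and sequence alignments, plus the
packaged study-scale scenario presets.

Coalescent trees are drawn by time-rescaling: with k active lineages the
waiting time to the next coalescence solves

    int_t^{t+w} C(k,2) / N(s) ds = E,   E ~ Exp(1),

inverted analytically for constant and exponential demographies and by
bisection for piecewise ones.  Heterochronous sampling inserts lineages at
their sampling heights.  Sequences evolve down the tree from a stationary
root state with per-branch transition matrices P(duration x clock x
category rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment
from .coalescent import DemographicGrid, inverse_pop_integral, pop_size_at
from .substitution import SiteRateModel, StrictClock, SubstitutionModel
from .tree import TimeTree

_BISECT_TOL = 1e-10


# ---------------------------------------------------------------------------
# demographic scenarios
# ---------------------------------------------------------------------------

@dataclass
class DemographicScenario:
    """Time-varying effective population size N(t), t = height in years.

    kinds: 'constant' (N0), 'exponential_growth' (N(t) = N0 exp(-rate*t),
    i.e. the population grew toward the present at rate `rate`), and
    'bottleneck' (N0 except Nb on [t_start, t_end)).
    """

    kind: str
    n0: float
    rate: float = 0.0
    nb: float = 1.0
    t_start: float = 0.0
    t_end: float = 0.0

    def pop_size(self, t: float) -> float:
        if t < 0:
            raise ValueError("time must be nonnegative")
        if self.kind == "constant":
            return self.n0
        if self.kind == "exponential_growth":
            return self.n0 * np.exp(-self.rate * t)
        if self.kind == "bottleneck":
            return self.nb if self.t_start <= t < self.t_end else self.n0
        raise ValueError(f"unknown scenario kind {self.kind!r}")

    def intensity(self, u: float, v: float) -> float:
        """int_u^v dt / N(t)."""
        if self.kind == "constant":
            return (v - u) / self.n0
        if self.kind == "exponential_growth":
            r = self.rate
            if r == 0:
                return (v - u) / self.n0
            return (np.exp(r * v) - np.exp(r * u)) / (r * self.n0)
        if self.kind == "bottleneck":
            total = 0.0
            for a, b, n in ((min(u, self.t_start), min(v, self.t_start), self.n0),
                            (np.clip(u, self.t_start, self.t_end),
                             np.clip(v, self.t_start, self.t_end), self.nb),
                            (max(u, self.t_end), max(v, self.t_end), self.n0)):
                if b > a:
                    total += (b - a) / n
            return total
        raise ValueError(f"unknown scenario kind {self.kind!r}")

    def waiting_time(self, t: float, target: float) -> float:
        """Solve intensity(t, t+w) = target for w."""
        if self.kind == "constant":
            return target * self.n0
        if self.kind == "exponential_growth":
            r = self.rate
            if r == 0:
                return target * self.n0
            # exp(r(t+w)) = exp(rt) + r N0 target
            return np.log(np.exp(r * t) + r * self.n0 * target) / r - t
        # piecewise: bisection on a bracket grown geometrically
        hi = max(self.n0, self.nb) * target + 1.0
        while self.intensity(t, t + hi) < target:
            hi *= 2.0
        lo = 0.0
        while hi - lo > _BISECT_TOL:
            mid = 0.5 * (lo + hi)
            if self.intensity(t, t + mid) < target:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    def grid_log_pop_sizes(self, grid_times) -> np.ndarray:
        return np.log([self.pop_size(t) for t in grid_times])


@dataclass
class GridDemography:
    """Adapter running the simulator directly under a fitted/true grid."""

    grid: DemographicGrid
    interpolation: str = "linear"

    def pop_size(self, t):
        return float(pop_size_at(self.grid, t, self.interpolation))

    def intensity(self, u, v):
        return float(inverse_pop_integral(self.grid, u, v, self.interpolation))

    def waiting_time(self, t, target):
        hi = 1.0
        while self.intensity(t, t + hi) < target:
            hi *= 2.0
        lo = 0.0
        while hi - lo > _BISECT_TOL:
            mid = 0.5 * (lo + hi)
            if self.intensity(t, t + mid) < target:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# coalescent tree simulation
# ---------------------------------------------------------------------------

def simulate_coalescent(demography, n_tips=None, sampling_heights=None,
                        rng=None, labels=None) -> TimeTree:
    """Draw a coalescent tree under an arbitrary demography.

    ``demography`` needs ``waiting_time(t, target)`` (inverse cumulative
    coalescent intensity); :class:`DemographicScenario` and
    :class:`GridDemography` both qualify.  Sampling heights default to
    isochronous at 0.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if sampling_heights is None:
        if n_tips is None or n_tips < 2:
            raise ValueError("need n_tips >= 2 or explicit sampling heights")
        sampling_heights = np.zeros(n_tips)
    sampling_heights = np.asarray(sampling_heights, dtype=float)
    n = len(sampling_heights)
    if n < 2:
        raise ValueError("need at least two tips")
    if np.any(sampling_heights < 0):
        raise ValueError("sampling heights must be nonnegative")
    if sampling_heights.min() > 0:
        raise ValueError("the youngest tip must be at height 0")
    if labels is None:
        labels = [f"t{i}" for i in range(n)]

    order = np.argsort(sampling_heights, kind="stable")
    pending = [(sampling_heights[i], int(i)) for i in order]
    children = np.zeros((n - 1, 2), dtype=int)
    heights = np.zeros(2 * n - 1)
    heights[:n] = sampling_heights

    t = 0.0
    active: list = []
    next_internal = n
    while next_internal < 2 * n - 1:
        while pending and pending[0][0] <= t:
            active.append(pending.pop(0)[1])
        k = len(active)
        if k < 2:
            # jump to the next sampling event
            t = pending[0][0]
            continue
        target = rng.exponential() / (k * (k - 1) / 2.0)
        w = demography.waiting_time(t, target)
        if pending and t + w > pending[0][0]:
            # a sampling event interrupts the waiting time; the memoryless
            # exponential lets us redraw past the event
            t = pending[0][0]
            continue
        t = t + w
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        active = [x for x in active if x not in (a, b)]
        children[next_internal - n] = [a, b]
        heights[next_internal] = t
        active.append(next_internal)
        next_internal += 1
    return TimeTree(labels, children, heights)


# ---------------------------------------------------------------------------
# sequence simulation
# ---------------------------------------------------------------------------

def simulate_alignment(tree: TimeTree, subst: SubstitutionModel,
                       sites: SiteRateModel, clock: StrictClock,
                       n_sites: int, rng=None) -> Alignment:
    """Evolve nucleotide sequences down the tree.

    Root states are drawn from the stationary frequencies; each site picks
    a rate category from the site model's weights.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n = tree.n_taxa
    cats = rng.choice(sites.n_categories, size=n_sites, p=sites.weights)
    states = np.empty((2 * n - 1, n_sites), dtype=int)
    states[tree.root] = rng.choice(4, size=n_sites, p=subst.frequencies)

    # transition matrices per branch and category
    for v in reversed(tree.postorder):
        for c in tree.children[v - tree.n_taxa]:
            dur = tree.heights[v] - tree.heights[c]
            for k in range(sites.n_categories):
                p = subst.transition_probs(dur * clock.rate * sites.rates[k])
                p = p / p.sum(axis=1, keepdims=True)
                mask = cats == k
                if not mask.any():
                    continue
                parent_states = states[v][mask]
                u = rng.random(parent_states.shape)
                cum = np.cumsum(p, axis=1)
                states[c][mask] = (u[:, None] > cum[parent_states]).sum(axis=1)

    alphabet = np.array(list("ACGT"))
    seqs = ["".join(alphabet[states[i]]) for i in range(n)]
    return Alignment.from_sequences(list(tree.taxa), seqs)


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

@dataclass
class ScenarioPreset:
    name: str
    config: dict
    scenario: DemographicScenario
    sampling_heights: np.ndarray
    n_sites: int
    simulation: dict = field(default_factory=dict)


def scenario_preset(name: str, n_tips: int = 20) -> ScenarioPreset:
    """Miniature study setups: an HCV-style and a SARS-CoV-2-style
    analysis, plus the three demographic validation scenarios.

    * ``hcv_like``: isochronous tips, GTR + discrete gamma(4), clock fixed
      at 7.9e-4 subst/site/year, grid coalescent (full-scale HCV analyses
      use a 400-year cutoff with 75 segments; scaled here to 8 segments).
    * ``sc2_like``: heterochronous tips, HKY with nonreversible random
      effects under a Bayesian bridge prior (exponent 0.25, gamma
      hyperprior shape 1 scale 2 on tau^-0.25), 5-segment skyglide with
      cutoff 0.3 years.
    * ``validation_constant`` / ``validation_growth`` /
      ``validation_bottleneck``: the three demographic recovery scenarios.
    """
    rngless = np.random.default_rng(12345)  # preset geometry, not data
    if name == "hcv_like":
        scenario = DemographicScenario("bottleneck", n0=20.0, nb=2.0,
                                       t_start=8.0, t_end=16.0)
        config = {
            "substitution": {"model": "gtr"},
            "site": {"model": "gamma", "categories": 4, "shape": 0.5},
            "clock": {"model": "strict", "rate": 7.9e-4, "fixed": True},
            "coalescent": {"model": "skyglide",
                           "grid": {"cutoff": 40.0, "segments": 8},
                           "gmrf": {"shape": 0.005, "rate": 0.005}},
            "objective": "elbo", "family": "mean_field",
            "iterations": 5000, "samples_per_step": 1, "learning_rate": 0.1,
        }
        return ScenarioPreset(name, config, scenario,
                              np.zeros(n_tips), 300,
                              {"kappa": None, "gtr_rates":
                               np.array([0.1, 0.3, 0.05, 0.1, 0.35, 0.1])})
    if name == "sc2_like":
        heights = np.concatenate([[0.0], np.sort(rngless.uniform(0, 0.25, n_tips - 1))])
        eps = np.zeros(12)
        eps[7] = 1.5   # C->T elevated
        eps[11] = 0.8  # G->T elevated
        scenario = DemographicScenario("exponential_growth", n0=0.5, rate=8.0)
        config = {
            "substitution": {"model": "hky", "kappa": 4.0, "random_effects": True,
                             "bridge": {"alpha": 0.25, "delta": 1.0, "scale": 2.0}},
            "site": {"model": "constant"},
            "clock": {"model": "strict", "rate": 1.0e-3, "fixed": True},
            "coalescent": {"model": "skyglide",
                           "grid": {"cutoff": 0.3, "segments": 5},
                           "gmrf": {"shape": 0.005, "rate": 0.005}},
            "objective": "elbo", "family": "mean_field",
            "iterations": 5000, "samples_per_step": 1, "learning_rate": 0.1,
        }
        return ScenarioPreset(name, config, scenario, heights, 500,
                              {"random_effects": eps})
    if name == "validation_constant":
        scenario = DemographicScenario("constant", n0=5.0)
    elif name == "validation_growth":
        scenario = DemographicScenario("exponential_growth", n0=10.0, rate=0.25)
    elif name == "validation_bottleneck":
        scenario = DemographicScenario("bottleneck", n0=10.0, nb=1.0,
                                       t_start=4.0, t_end=8.0)
    else:
        raise ValueError(f"unknown preset {name!r}")
    config = {
        "substitution": {"model": "jc69"},
        "site": {"model": "constant"},
        "clock": {"model": "strict", "rate": 0.01, "fixed": True},
        "coalescent": {"model": "skyglide",
                       "grid": {"cutoff": 20.0, "segments": 8},
                       "gmrf": {"shape": 0.005, "rate": 0.005}},
        "objective": "elbo", "family": "mean_field",
        "iterations": 4000, "samples_per_step": 1, "learning_rate": 0.1,
    }
    return ScenarioPreset(name, config, scenario, np.zeros(n_tips), 300, {})


VALIDATION_PRESETS = ("validation_constant", "validation_growth",
                      "validation_bottleneck")
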