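"""Packaged desk-scale experiments.

The sharp-change experiment is a miniature of the empirical contrast
between the two grid coalescent models under gradient-based and
gradient-free variational inference: sequence data are simulated on a
heterochronous coalescent genealogy whose effective population size drops
abruptly going into the past, and each inference arm is scored on whether
its 95% interval for the root height covers the truth.  The
piecewise-constant model's jump discontinuities are what stress the
gradient-based (ELBO) arm; the forward-KL arm never differentiates the
model and is indifferent to them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import build_model
from .inference import MeanFieldGaussian, fit_vi, map_optimize
from .posterior import JointPosterior
from .simulate import DemographicScenario, simulate_alignment, simulate_coalescent
from .substitution import JC69, StrictClock, constant_rates
from .tree import TimeTree

# study conditions for the sharp-change twin: 16 tips sampled over 3 years,
# N(t) = 5 for t < 4 dropping to 0.5 beyond, 200 sites, clock 0.02
SHARP_CHANGE = {
    "n_tips": 16,
    "sampling_window": 3.0,
    "n_recent": 5.0,
    "n_ancient": 0.5,
    "change_time": 4.0,
    "n_sites": 200,
    "clock_rate": 0.02,
    "grid_cutoff": 8.0,
    "grid_segments": 6,
}


def sharp_change_scenario() -> DemographicScenario:
    c = SHARP_CHANGE
    return DemographicScenario("bottleneck", n0=c["n_ancient"], nb=c["n_recent"],
                               t_start=0.0, t_end=c["change_time"])


def simulate_sharp_change(seed: int):
    """(tree, alignment, true root height) for one replicate."""
    c = SHARP_CHANGE
    rng = np.random.default_rng(seed)
    heights = np.concatenate([[0.0],
                              rng.uniform(0, c["sampling_window"], c["n_tips"] - 1)])
    tree = simulate_coalescent(sharp_change_scenario(), sampling_heights=heights,
                               rng=rng)
    aln = simulate_alignment(tree, JC69(), constant_rates(),
                             StrictClock(c["clock_rate"]), c["n_sites"], rng)
    return tree, aln, float(tree.heights[tree.root])


def sharp_change_config(coalescent_model: str) -> dict:
    c = SHARP_CHANGE
    return {"substitution": {"model": "jc69"},
            "site": {"model": "constant"},
            "clock": {"model": "strict", "rate": c["clock_rate"], "fixed": True},
            "coalescent": {"model": coalescent_model,
                           "grid": {"cutoff": c["grid_cutoff"],
                                    "segments": c["grid_segments"]}}}


def root_height_interval(model: JointPosterior, tree: TimeTree,
                         q: MeanFieldGaussian, level: float = 0.95):
    """Central credible interval for the root height under a mean-field
    fit: the root-excess coordinate is log-normally distributed."""
    from scipy.stats import norm
    i = model.slices["heights"].start  # slot 0 of the heights block
    zq = norm.ppf(0.5 + level / 2.0)
    lb = tree.lower_bounds()[tree.root]
    mu, sd = q.mu[i], np.exp(q.log_sigma[i])
    return lb + np.exp(mu - zq * sd), lb + np.exp(mu + zq * sd)


@dataclass
class CoverageArm:
    objective: str
    coalescent: str
    interval: tuple
    covered: bool


def sharp_change_replicate(seed: int, iterations: int = 2500,
                           arms=(("elbo", "skyglide"),
                                 ("forward_kl", "skyglide"),
                                 ("forward_kl", "skygrid"))):
    """Run all inference arms on one simulated replicate.

    Each arm warm-starts the variational mean at the MAP of its own model
    (the optimized parameters play the role of the long optimization runs
    of the full-scale analyses) and reports root-height coverage.
    """
    tree, aln, true_root = simulate_sharp_change(seed)
    results = []
    maps = {}
    for objective, coal in arms:
        cfg = sharp_change_config(coal)
        if coal not in maps:
            maps[coal] = map_optimize(build_model(cfg, aln, tree)).x
        model = build_model(cfg, aln, tree)
        q, _ = fit_vi(model, objective=objective, iterations=iterations,
                      seed=seed, init_mu=maps[coal], init_sigma=0.05)
        lo, hi = root_height_interval(model, tree, q)
        results.append(CoverageArm(objective, coal, (float(lo), float(hi)),
                                   bool(lo <= true_root <= hi)))
    return true_root, results
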