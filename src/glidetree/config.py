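"""Run configuration (JSON) and assembly of the phylogenetic joint
posterior from its blocks.

The JSON schema is this package's own; it mirrors the block structure of
the analyses (substitution / site / clock / coalescent plus inference
settings) — see README for the documented schema.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .alignment import Alignment
from .coalescent import (DemographicGrid, coalescent_log_density_heights,
                         constant_coalescent_log_density_heights, gmrf_log_prior)
from .likelihood import pruning_log_likelihood
from .posterior import JointPosterior, ParameterBlock
from .priors import bridge_log_density, dirichlet_logpdf, gamma_logpdf, lognormal_logpdf
from .substitution import gamma_rates_ad, weibull_rates_raw
from .transforms import (HeightRatioTransform, Identity, LogPositive,
                         StickBreakingSimplex)
from .tree import TimeTree


class ConfigError(ValueError):
    pass


_OBJECTIVES = ("elbo", "forward_kl")
_FAMILIES = ("mean_field", "full_rank")


@dataclass
class RunConfig:
    """Validated analysis configuration."""

    seed: int = 0
    iterations: int = 5000
    learning_rate: float | None = None
    objective: str = "elbo"
    family: str = "mean_field"
    samples_per_step: int | None = None
    substitution: dict = field(default_factory=lambda: {"model": "jc69"})
    site: dict = field(default_factory=lambda: {"model": "constant"})
    clock: dict = field(default_factory=lambda: {"model": "strict", "rate": 1.0,
                                                 "fixed": True})
    coalescent: dict = field(default_factory=lambda: {"model": "constant"})
    data: dict = field(default_factory=dict)   # alignment/tree/dates paths
    output: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.objective not in _OBJECTIVES:
            raise ConfigError(f"objective must be one of {_OBJECTIVES}")
        if self.family not in _FAMILIES:
            raise ConfigError(f"family must be one of {_FAMILIES}")
        if self.iterations < 1:
            raise ConfigError("iterations must be >= 1")
        if self.learning_rate is not None and self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            try:
                d = json.load(fh)
            except json.JSONDecodeError as err:
                raise ConfigError(f"malformed JSON in {path}: {err}")
        return cls.from_dict(d)

    def to_json(self, path) -> None:
        d = {f: getattr(self, f) for f in self.__dataclass_fields__}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, default=_jsonable)


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    raise TypeError(f"not JSON serializable: {type(x)}")


def build_model(config, aln: Alignment, tree: TimeTree) -> JointPosterior:
    """Wire likelihoods, priors and transforms into a joint posterior.

    Fixed parameters (e.g. a fixed clock rate) are closed over as
    constants and never enter the unconstrained vector.
    """
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    n = tree.n_taxa
    blocks = [ParameterBlock("heights", HeightRatioTransform(tree))]
    terms = []

    # -- substitution block ----------------------------------------------
    sub = dict(config.substitution)
    model_name = sub.get("model", "jc69").lower()
    has_re = bool(sub.get("random_effects", False))
    if model_name not in ("jc69", "hky", "gtr"):
        raise ConfigError(f"unknown substitution model {model_name!r}")
    if model_name == "jc69":
        if has_re:
            raise ConfigError("random effects require hky or gtr")
        freqs_fn = lambda values: np.full(4, 0.25)
    else:
        blocks.append(ParameterBlock("frequencies", StickBreakingSimplex(4),
                                     prior=dirichlet_logpdf))
        freqs_fn = lambda values: values["frequencies"]
    if model_name == "hky":
        if sub.get("kappa_fixed", False):
            kappa_const = float(sub.get("kappa", 2.0))
            kappa_fn = lambda values: kappa_const
        else:
            blocks.append(ParameterBlock(
                "kappa", LogPositive(1),
                prior=lambda x: lognormal_logpdf(x[0], 1.0, 1.25)))
            kappa_fn = lambda values: values["kappa"][0]
    else:
        kappa_fn = lambda values: None
    if model_name == "gtr":
        blocks.append(ParameterBlock("gtr_rates", StickBreakingSimplex(6),
                                     prior=dirichlet_logpdf))
        rates_fn = lambda values: values["gtr_rates"]
    else:
        rates_fn = lambda values: None
    if has_re:
        bridge = sub.get("bridge", {})
        alpha = float(bridge.get("alpha", 0.25))
        delta = float(bridge.get("delta", 1.0))
        scale = float(bridge.get("scale", 2.0))
        blocks.append(ParameterBlock("random_effects", Identity(12)))
        # nu = tau^(-alpha) carries the gamma hyperprior
        blocks.append(ParameterBlock(
            "bridge_nu", LogPositive(1),
            prior=lambda x: gamma_logpdf(x[0], delta, 1.0 / scale)))

        def bridge_term(values):
            tau = ad.power(values["bridge_nu"][0], -1.0 / alpha)
            return bridge_log_density(values["random_effects"], tau, alpha)

        terms.append(("prior:bridge", bridge_term))
        effects_fn = lambda values: values["random_effects"]
    else:
        effects_fn = lambda values: None

    # -- site model --------------------------------------------------------
    site = dict(config.site)
    site_model = site.get("model", "constant").lower()
    n_cat = int(site.get("categories", 4))
    if site_model in ("constant", "none"):
        site_rates_fn = lambda values: (np.ones(1), np.ones(1))
    elif site_model in ("gamma", "weibull"):
        if site.get("shape_fixed", False):
            shape_const = float(site.get("shape", 0.5))
            if site_model == "gamma":
                site_rates_fn = lambda values: (
                    gamma_rates_ad(shape_const, n_cat), np.full(n_cat, 1.0 / n_cat))
            else:
                site_rates_fn = lambda values: (
                    weibull_rates_raw(shape_const, n_cat), np.full(n_cat, 1.0 / n_cat))
        else:
            blocks.append(ParameterBlock(
                "site_shape", LogPositive(1),
                prior=lambda x: gamma_logpdf(x[0], 1.0, 1.0)))  # Exp(1)
            if site_model == "gamma":
                site_rates_fn = lambda values: (
                    gamma_rates_ad(values["site_shape"][0], n_cat),
                    np.full(n_cat, 1.0 / n_cat))
            else:
                site_rates_fn = lambda values: (
                    weibull_rates_raw(values["site_shape"][0], n_cat),
                    np.full(n_cat, 1.0 / n_cat))
    else:
        raise ConfigError(f"unknown site model {site_model!r}")

    # -- clock -------------------------------------------------------------
    clock = dict(config.clock)
    if clock.get("model", "strict") != "strict":
        raise ConfigError("only the strict clock is implemented")
    if clock.get("fixed", False):
        if "rate" not in clock:
            raise ConfigError("fixed clock requires a rate")
        rate_const = float(clock["rate"])
        clock_fn = lambda values: rate_const
    else:
        blocks.append(ParameterBlock("clock_rate", LogPositive(1)))
        clock_fn = lambda values: values["clock_rate"][0]

    # -- coalescent --------------------------------------------------------
    coal = dict(config.coalescent)
    coal_model = coal.get("model", "constant").lower()
    tip_heights = tree.heights[:n].copy()

    def coal_heights(heights):
        return heights[n:]

    if coal_model == "constant":
        blocks.append(ParameterBlock("pop_size", LogPositive(1)))

        def coalescent_term(values):
            return constant_coalescent_log_density_heights(
                tip_heights, coal_heights(values["heights"]), values["pop_size"][0])

        terms.append(("coalescent", coalescent_term))
    elif coal_model in ("skygrid", "skyglide"):
        grid_cfg = coal.get("grid")
        if not grid_cfg or "cutoff" not in grid_cfg or "segments" not in grid_cfg:
            raise ConfigError(f"{coal_model} requires grid.cutoff and grid.segments")
        cutoff = float(grid_cfg["cutoff"])
        segments = int(grid_cfg["segments"])
        kind = "linear" if coal_model == "skyglide" else "constant"
        gmrf_cfg = coal.get("gmrf", {})
        gmrf_shape = float(gmrf_cfg.get("shape", 0.005))
        gmrf_rate = float(gmrf_cfg.get("rate", 0.005))
        blocks.append(ParameterBlock("log_pop_sizes", Identity(segments + 1)))
        blocks.append(ParameterBlock(
            "gmrf_precision", LogPositive(1),
            prior=lambda x: gamma_logpdf(x[0], gmrf_shape, gmrf_rate)))

        def coalescent_term(values):
            grid = DemographicGrid(cutoff, segments, values["log_pop_sizes"])
            return coalescent_log_density_heights(
                tip_heights, coal_heights(values["heights"]), grid, kind)

        def gmrf_term(values):
            return gmrf_log_prior(values["log_pop_sizes"],
                                  values["gmrf_precision"][0])

        terms.append(("coalescent", coalescent_term))
        terms.append(("prior:gmrf", gmrf_term))
    else:
        raise ConfigError(f"unknown coalescent model {coal_model!r}")

    # -- tree likelihood ---------------------------------------------------
    from .substitution import build_rate_matrix

    def likelihood_term(values):
        freqs = freqs_fn(values)
        if model_name == "jc69":
            q = None  # closed-form JC69 transition probabilities
        else:
            q = build_rate_matrix(model_name, freqs, kappa=kappa_fn(values),
                                  rates=rates_fn(values),
                                  random_effects=effects_fn(values))
        site_rates, site_weights = site_rates_fn(values)
        return pruning_log_likelihood(tree, aln, q, freqs, site_rates,
                                      site_weights, clock_fn(values),
                                      heights=values["heights"])

    terms.insert(0, ("tree_likelihood", likelihood_term))
    return JointPosterior(blocks, terms)
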