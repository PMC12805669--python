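"""Coalescent log-densities under constant, piecewise-constant (skygrid)
and piecewise-linear (skyglide) demographic functions, plus the GMRF
smoothing prior on log population sizes.

Both grid models share the same parameterization: effective population
sizes theta_i = exp(gamma_i) at M+1 equidistant grid times 0 = x_0 < ... <
x_M = C (C the cutoff, in years, anchored at the height of the most recent
tip).  The skygrid holds theta constant within each cell and therefore has
jump discontinuities at the grid times; the skyglide interpolates linearly
between the grid values and is continuous everywhere, which is what makes
it usable with gradient-based inference.  Beyond the cutoff both models
extend theta_M as a constant.

The heterochronous coalescent density, with lineage count k(t) piecewise
constant between sampling and coalescence events, is

    log p = sum_events [ log C(k,2) - log N(t_c) ]  (coalescences only)
            - sum_intervals C(k,2) * int_interval dt / N(t)

Sampling events contribute no point mass.  All arithmetic goes through the
autodiff dispatch layer, so the same code serves plain evaluation and the
differentiable joint posterior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .tree import CoalescentIntervals, TimeTree

LOG_2PI = float(np.log(2.0 * np.pi))

# relative slope threshold below which a linear cell is integrated as
# constant, avoiding catastrophic cancellation in (1/b) log-ratio
_SLOPE_TOL = 1e-12


class CoalescentError(ValueError):
    pass


@dataclass
class DemographicGrid:
    """Equidistant grid of log effective population sizes.

    ``log_pop_sizes`` may be a plain array or an autodiff tensor of length
    ``segments + 1``.
    """

    cutoff: float
    segments: int
    log_pop_sizes: object

    def __post_init__(self):
        if self.cutoff <= 0:
            raise CoalescentError("cutoff must be positive")
        if self.segments < 1:
            raise CoalescentError("need at least one segment")
        if len(ad.value_of(self.log_pop_sizes)) != self.segments + 1:
            raise CoalescentError("need segments + 1 population sizes")

    @property
    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.cutoff, self.segments + 1)

    @property
    def delta(self) -> float:
        return self.cutoff / self.segments

    def theta(self, i):
        return ad.exp(self.log_pop_sizes[i])


def _cell_index(grid: DemographicGrid, t: float) -> int:
    """Grid cell containing time t (clamped to the last cell beyond C)."""
    return min(int(np.floor(t / grid.delta)), grid.segments - 1)


def pop_size_at(grid: DemographicGrid, t, kind: str):
    """N(t) under the requested interpolation.

    kind='linear' (skyglide): continuous interpolation between grid values;
    kind='constant' (skygrid): left-value step function with jumps at the
    grid times.  Beyond the cutoff both return theta_M.
    """
    tv = float(ad.value_of(t))
    if tv < 0:
        raise CoalescentError("time must be nonnegative")
    if tv >= grid.cutoff:
        return grid.theta(grid.segments)
    i = _cell_index(grid, tv)
    if kind == "constant":
        return grid.theta(i)
    if kind != "linear":
        raise CoalescentError(f"unknown interpolation kind {kind!r}")
    x = grid.times
    th_i, th_j = grid.theta(i), grid.theta(i + 1)
    frac = ad.div(ad.sub(t, x[i]), x[i + 1] - x[i])
    return ad.add(th_i, ad.mul(ad.sub(th_j, th_i), frac))


def _cell_integral(grid: DemographicGrid, i: int, a, b, kind: str):
    """int_a^b dt / N(t) within cell i (or the constant tail for i >= M)."""
    if i >= grid.segments:
        return ad.div(ad.sub(b, a), grid.theta(grid.segments))
    if kind == "constant":
        return ad.div(ad.sub(b, a), grid.theta(i))
    th_i = grid.theta(i)
    th_j = grid.theta(i + 1)
    slope = ad.div(ad.sub(th_j, th_i), grid.delta)
    x0 = grid.times[i]
    n_a = ad.add(th_i, ad.mul(slope, ad.sub(a, x0)))
    if abs(float(ad.value_of(slope))) < _SLOPE_TOL * float(ad.value_of(th_i)):
        # flat cell: constant fallback at the left endpoint value
        return ad.div(ad.sub(b, a), n_a)
    n_b = ad.add(th_i, ad.mul(slope, ad.sub(b, x0)))
    return ad.div(ad.sub(ad.log(n_b), ad.log(n_a)), slope)


def inverse_pop_integral(grid: DemographicGrid, u, v, kind: str):
    """int_u^v dt / N(t), splitting [u, v] at the grid times."""
    uv, vv = float(ad.value_of(u)), float(ad.value_of(v))
    if uv < 0 or vv < uv:
        raise CoalescentError("need 0 <= u <= v")
    if vv == uv:
        return 0.0
    cuts = grid.times[(grid.times > uv) & (grid.times < vv)]
    points = [u] + list(cuts) + [v]
    total = 0.0
    for a, b in zip(points[:-1], points[1:]):
        # index the cell by the segment midpoint: robust to floating-point
        # jitter when an endpoint sits exactly on a grid time
        mid = 0.5 * (float(ad.value_of(a)) + float(ad.value_of(b)))
        i = grid.segments if mid >= grid.cutoff else _cell_index(grid, mid)
        total = ad.add(total, _cell_integral(grid, i, a, b, kind))
    return total


def _log_binom2(k: int) -> float:
    return float(np.log(k * (k - 1) / 2.0))


def coalescent_log_density(intervals: CoalescentIntervals,
                           grid: DemographicGrid, kind: str):
    """Heterochronous coalescent log-density from precomputed intervals."""
    if len(intervals.starts) and intervals.starts[0] < 0:
        raise CoalescentError("interval extends below height 0")
    total = 0.0
    for a, b, k in zip(intervals.starts, intervals.ends, intervals.lineage_counts):
        if k >= 2:
            total = ad.sub(total, ad.mul(k * (k - 1) / 2.0,
                                         inverse_pop_integral(grid, a, b, kind)))
    for t_c, k in zip(intervals.coalescent_heights, intervals.coalescent_lineages):
        total = ad.add(total, _log_binom2(int(k)))
        total = ad.sub(total, ad.log(pop_size_at(grid, t_c, kind)))
    return total


def _as_vector(xs):
    if isinstance(xs, ad.Tensor) or isinstance(xs, np.ndarray):
        return xs
    if any(isinstance(x, ad.Tensor) for x in xs):
        return ad.stack(list(xs))
    return np.asarray(xs, dtype=float)


def _event_bookkeeping(tip_heights, coal_values):
    """Sorted event order and per-interval lineage counts (all detached).

    Sampling events are processed before coalescences at equal heights so
    every coalescence sees k >= 2.
    """
    n_tips = len(tip_heights)
    vals = np.concatenate([np.asarray(tip_heights, dtype=float), coal_values])
    is_coal = np.concatenate([np.zeros(n_tips, dtype=int),
                              np.ones(len(coal_values), dtype=int)])
    perm = np.lexsort((is_coal, vals))
    counts = np.empty(len(vals) - 1, dtype=int)
    coal_counts = {}
    k = 0
    for pos, idx in enumerate(perm):
        if is_coal[idx]:
            coal_counts[idx - n_tips] = k
            k -= 1
        else:
            k += 1
        if pos < len(counts):
            counts[pos] = k
    coal_k = np.array([coal_counts[i] for i in range(len(coal_values))], dtype=int)
    if np.any(coal_k < 2):
        raise CoalescentError("coalescence with fewer than two lineages")
    return perm, counts, coal_k


def _grid_eval(grid: DemographicGrid, kind: str, times):
    """Vectorized (N(t), I(t) = int_0^t dt'/N) at differentiable times.

    Cell membership and degenerate-slope masks are detached (they are
    piecewise-constant in the parameters); all value arithmetic stays in
    the graph.
    """
    tv = np.asarray(ad.value_of(times), dtype=float)
    M = grid.segments
    x = grid.times
    delta = grid.delta
    theta = ad.exp(grid.log_pop_sizes)
    log_theta = grid.log_pop_sizes

    in_tail = (tv >= grid.cutoff).astype(float)
    cells = np.minimum((tv // delta).astype(int), M - 1)
    # the in-grid branch sees times clamped at the cutoff so the (masked
    # out) linear extrapolation can never go negative and poison the
    # graph with NaN; the tail branch keeps the raw times
    times_in = ad.add(ad.mul(1.0 - in_tail, times), in_tail * grid.cutoff)

    if kind == "constant":
        cell_int = ad.div(delta, theta[:-1])                     # (M,)
        th_c = theta[cells]
        partial = ad.div(ad.sub(times_in, x[cells]), th_c)
        n_at = th_c
    else:
        slope = ad.div(ad.sub(theta[1:], theta[:-1]), delta)
        sv = np.asarray(ad.value_of(slope))
        thv = np.asarray(ad.value_of(theta))
        flat = (np.abs(sv) < _SLOPE_TOL * thv[:-1]).astype(float)
        safe_slope = ad.add(slope, flat)  # keeps the unselected branch finite
        log_ratio = ad.sub(log_theta[1:], log_theta[:-1])
        cell_int = ad.add(ad.mul(1.0 - flat, ad.div(log_ratio, safe_slope)),
                          ad.mul(flat, ad.div(delta, theta[:-1])))
        th_c = theta[cells]
        sl_c = slope[cells]
        n_at = ad.add(th_c, ad.mul(sl_c, ad.sub(times_in, x[cells])))
        flat_c = flat[cells]
        safe_sl_c = ad.add(sl_c, flat_c)
        lin = ad.div(ad.sub(ad.log(n_at), ad.log(th_c)), safe_sl_c)
        partial = ad.add(ad.mul(1.0 - flat_c, lin),
                         ad.mul(flat_c, ad.div(ad.sub(times_in, x[cells]), th_c)))

    # cumulative full-cell integrals: cum[i] = sum of cells < i
    lower = np.tril(np.ones((M + 1, M)), -1)
    cum = ad.einsum("ij,j->i", lower, cell_int)
    inside = ad.add(cum[cells], partial)
    tail = ad.add(cum[M], ad.div(ad.sub(times, grid.cutoff), theta[M]))
    integral = ad.add(ad.mul(1.0 - in_tail, inside), ad.mul(in_tail, tail))
    n_t = ad.add(ad.mul(1.0 - in_tail, n_at), ad.mul(in_tail, theta[M]))
    return n_t, integral


def coalescent_log_density_heights(tip_heights, coal_heights,
                                   grid: DemographicGrid, kind: str):
    """Heterochronous coalescent log-density with differentiable event
    heights (vector or sequence of scalars; tensors for AD).  The event
    ordering is recomputed from current values."""
    if kind not in ("linear", "constant"):
        raise CoalescentError(f"unknown interpolation kind {kind!r}")
    coal = _as_vector(coal_heights)
    coal_values = np.atleast_1d(np.asarray(ad.value_of(coal), dtype=float))
    perm, counts, coal_k = _event_bookkeeping(tip_heights, coal_values)

    times = ad.concatenate([np.asarray(tip_heights, dtype=float),
                            coal if isinstance(coal, ad.Tensor) else coal_values])
    n_coal, integral_at = _grid_eval(grid, kind, times)
    i_sorted = integral_at[perm]
    d_i = ad.sub(i_sorted[1:], i_sorted[:-1])
    w = counts * (counts - 1) / 2.0
    total = ad.mul(-1.0, ad.asum(ad.mul(w, d_i)))

    n_tips = len(tip_heights)
    log_n_coal = ad.log(n_coal[n_tips:])
    total = ad.sub(total, ad.asum(log_n_coal))
    total = ad.add(total, float(np.sum([_log_binom2(int(k)) for k in coal_k])))
    return total


def constant_coalescent_log_density(intervals: CoalescentIntervals, theta):
    """Closed-form constant-N density; theta may be an autodiff tensor."""
    total = 0.0
    for a, b, k in zip(intervals.starts, intervals.ends, intervals.lineage_counts):
        if k >= 2:
            total = ad.sub(total, ad.div(ad.mul(k * (k - 1) / 2.0, b - a), theta))
    for k in intervals.coalescent_lineages:
        total = ad.add(total, _log_binom2(int(k)))
        total = ad.sub(total, ad.log(theta))
    return total


def constant_coalescent_log_density_heights(tip_heights, coal_heights, theta):
    """Constant-N analogue of :func:`coalescent_log_density_heights`."""
    coal = _as_vector(coal_heights)
    coal_values = np.atleast_1d(np.asarray(ad.value_of(coal), dtype=float))
    perm, counts, coal_k = _event_bookkeeping(tip_heights, coal_values)
    times = ad.concatenate([np.asarray(tip_heights, dtype=float),
                            coal if isinstance(coal, ad.Tensor) else coal_values])
    t_sorted = times[perm]
    d_t = ad.sub(t_sorted[1:], t_sorted[:-1])
    w = counts * (counts - 1) / 2.0
    total = ad.mul(-1.0, ad.div(ad.asum(ad.mul(w, d_t)), theta))
    total = ad.sub(total, ad.mul(float(len(coal_values)), ad.log(theta)))
    return ad.add(total, float(np.sum([_log_binom2(int(k)) for k in coal_k])))


def gmrf_log_prior(gammas, kappa):
    """Intrinsic Gaussian Markov random field on adjacent differences:

        (M/2) log(kappa / 2 pi) - (kappa/2) sum_i (gamma_{i+1} - gamma_i)^2

    with M = len(gamma) - 1.  Shift-invariant in the level of gamma.
    """
    if float(ad.value_of(kappa)) <= 0:
        raise CoalescentError("GMRF precision must be positive")
    g = gammas
    m = len(ad.value_of(gammas)) - 1
    diffs = ad.sub(g[1:], g[:-1])
    quad = ad.asum(ad.mul(diffs, diffs))
    return ad.sub(ad.mul(m / 2.0, ad.sub(ad.log(kappa), LOG_2PI)),
                  ad.mul(ad.div(kappa, 2.0), quad))


@dataclass
class GMRFPrior:
    """GMRF smoothing prior with a gamma hyperprior on the precision.

    The conventional skygrid hyperprior is Gamma(shape=0.005, rate=0.005);
    both hyperparameters are configurable.
    """

    precision_shape: float = 0.005
    precision_rate: float = 0.005

    def log_prior(self, gammas, kappa):
        return gmrf_log_prior(gammas, kappa)

    def log_hyperprior(self, kappa):
        from .priors import gamma_logpdf
        return gamma_logpdf(kappa, self.precision_shape, self.precision_rate)
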