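"""Felsenstein pruning log-likelihood.

The core routine is written against the autodiff dispatch layer: called
with plain arrays it evaluates with numpy only; called with tensors it
yields a differentiable graph (reverse-mode AD through the pruning
recursion, including the matrix exponentials).

Per-pattern rescaling guards against underflow: whenever the largest
partial of a pattern drops below 1e-40 the column is divided by its
(detached) maximum and the log factor is added back at the root.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .alignment import Alignment
from .substitution import SiteRateModel, StrictClock, SubstitutionModel, build_rate_matrix
from .tree import TimeTree

_UNDERFLOW = 1e-40


class LikelihoodError(ValueError):
    pass


def pruning_log_likelihood(tree: TimeTree, aln: Alignment, q, frequencies,
                           site_rates, site_weights, clock_rate, heights=None):
    """Log-likelihood of the alignment by postorder pruning.

    Parameters
    ----------
    q : 4x4 normalized rate matrix (array or tensor), or None for the
        Jukes-Cantor closed-form transition probabilities (fast path).
    frequencies : root state weights (the stationary frequencies);
        ignored when q is None.
    site_rates, site_weights : per-category rates (mean 1) and weights.
    clock_rate : scalar (array or tensor).
    heights : optional replacement heights vector (tensor for AD); defaults
        to the tree's stored heights.
    """
    if sorted(aln.taxa) != sorted(tree.taxa):
        raise LikelihoodError("tree and alignment taxa differ")
    n = tree.n_taxa
    h = tree.heights if heights is None else heights
    weights = np.asarray(aln.pattern_weights, dtype=float)
    K = len(ad.value_of(site_rates))

    child_idx = np.array([v for v in range(2 * n - 1) if v != tree.root])
    par_idx = tree.parent[child_idx]
    dur = ad.sub(h[par_idx], h[child_idx])
    if np.any(np.asarray(ad.value_of(dur)) < -1e-12):
        bad = child_idx[np.argmin(np.asarray(ad.value_of(dur)))]
        raise LikelihoodError(f"negative branch duration at node {bad}")
    scaled_rates = ad.mul(site_rates, clock_rate)
    ts = ad.einsum("b,k->bk", dur, scaled_rates)

    # per-branch, per-category transition matrices
    mats = {}
    if q is None:
        # Jukes-Cantor closed form: P(t) = 1/4 + (I - 1/4) exp(-4t/3),
        # vectorized over branches and categories
        e = ad.exp(ad.mul(ts, -4.0 / 3.0))
        p_all = ad.add(0.25, ad.einsum("bk,ij->bkij", e, np.eye(4) - 0.25))
        frequencies = np.full(4, 0.25)
        for b, v in enumerate(child_idx):
            mats[v] = p_all[b]
    else:
        for b, v in enumerate(child_idx):
            per_cat = [ad.expm(ad.mul(q, ts[b, k])) for k in range(K)]
            mats[v] = ad.stack(per_cat)

    tip_partials = {i: aln.tip_partials(tree.taxa[i]) for i in range(n)}

    partials = {}
    log_scalers = np.zeros(len(aln.patterns))
    for v in tree.postorder:
        msg = None
        for c in tree.children[v - n]:
            if c < n:
                m = ad.einsum("kij,pj->pki", mats[c], tip_partials[c])
            else:
                m = ad.einsum("kij,pkj->pki", mats[c], partials[c])
            msg = m if msg is None else ad.mul(msg, m)
        vals = ad.value_of(msg)
        col_max = vals.max(axis=(1, 2))
        if np.any(col_max < _UNDERFLOW):
            if np.any(col_max <= 0):
                raise LikelihoodError("zero partial likelihood column")
            scale = np.where(col_max < _UNDERFLOW, col_max, 1.0)
            msg = ad.div(msg, scale[:, None, None])
            log_scalers += np.log(scale)
        partials[v] = msg

    site_lik = ad.einsum("pki,i->pk", partials[tree.root], frequencies)
    per_pattern = ad.einsum("pk,k->p", site_lik, site_weights)
    total = ad.asum(ad.mul(ad.log(per_pattern), weights))
    return ad.add(total, float(weights @ log_scalers))


def tree_log_likelihood(tree: TimeTree, aln: Alignment, subst: SubstitutionModel,
                        sites: SiteRateModel, clock: StrictClock) -> float:
    """Plain-number convenience wrapper around the pruning routine."""
    q = build_rate_matrix(subst.name, subst.frequencies, subst.kappa,
                          subst.rates, subst.random_effects)
    val = pruning_log_likelihood(tree, aln, q, subst.frequencies,
                                 sites.rates, sites.weights, clock.rate)
    return float(ad.value_of(val))
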