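"""Assembly of the unnormalized log joint density on the unconstrained
parameter scale.

A :class:`JointPosterior` is an ordered list of parameter blocks (each a
named slice of the global unconstrained vector with a bijective transform
and an optional prior on the constrained value) plus density terms
(likelihoods and joint priors) evaluated on the constrained values.  The
log joint is

    sum_blocks [ log|det J_block| + log prior(constrained) ]
    + sum_terms log term(values)

which is the density of the constrained model pulled back to the
unconstrained space.  Fixed parameters are not blocks at all; builders
close over their constants, so the gradient vector carries no dead slots.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad


class NumericError(RuntimeError):
    pass


class ParameterBlock:
    def __init__(self, name: str, transform, prior=None):
        self.name = name
        self.transform = transform
        self.prior = prior
        self.size = transform.size


class JointPosterior:
    """Callable log joint with slice bookkeeping and gradient accounting.

    ``gradient_evals`` counts every differentiated evaluation; the
    forward-KL objective must leave it untouched (that objective needs only
    plain density evaluations).
    """

    def __init__(self, blocks, terms):
        self.blocks = list(blocks)
        self.terms = list(terms)
        self.slices = {}
        offset = 0
        for b in self.blocks:
            self.slices[b.name] = slice(offset, offset + b.size)
            offset += b.size
        self.dim = offset
        self.gradient_evals = 0

    # -- evaluation --------------------------------------------------------
    def _pieces(self, x):
        """(values dict, list of (label, scalar)) for a vector or tensor.

        Domain failures inside a term (an inadmissible point proposed by an
        optimizer or sampler) surface as NumericError so callers can treat
        the point as having zero posterior mass."""
        values = {}
        pieces = []
        for b in self.blocks:
            y = x[self.slices[b.name]]
            constrained, logj = b.transform.forward(y)
            values[b.name] = constrained
            pieces.append((f"jacobian:{b.name}", logj))
            if b.prior is not None:
                pieces.append((f"prior:{b.name}", b.prior(constrained)))
        for name, fn in self.terms:
            try:
                pieces.append((name, fn(values)))
            except NumericError:
                raise
            except (ValueError, FloatingPointError, OverflowError) as err:
                raise NumericError(f"term {name!r} failed: {err}")
        return values, pieces

    def log_joint(self, x: np.ndarray) -> float:
        """Plain (gradient-free) evaluation."""
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            _, pieces = self._pieces(np.asarray(x, dtype=float))
        total = 0.0
        for label, val in pieces:
            v = float(ad.value_of(val))
            if not np.isfinite(v):
                raise NumericError(f"non-finite log-density term {label!r}")
            total += v
        return total

    def log_joint_grad(self, x: np.ndarray):
        """(value, gradient) via reverse-mode AD."""
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            xt = ad.Tensor.param(np.asarray(x, dtype=float))
            total = self._expr(xt)
            (g,) = ad.grad(total, [xt])
        v = float(total.value)
        if not np.isfinite(v) or not np.all(np.isfinite(g)):
            raise NumericError("non-finite log joint or gradient")
        return v, g

    def _expr(self, xt):
        """Scalar autodiff expression of the log joint (for embedding in
        larger graphs, e.g. the pathwise ELBO)."""
        if isinstance(xt, ad.Tensor) and xt.needs:
            self.gradient_evals += 1
        _, pieces = self._pieces(xt)
        total = 0.0
        for label, val in pieces:
            if not np.isfinite(float(ad.value_of(val))):
                raise NumericError(f"non-finite log-density term {label!r}")
            total = ad.add(total, val)
        return total

    # -- parameter plumbing ------------------------------------------------
    def constrain(self, x: np.ndarray) -> dict:
        values, _ = self._pieces(np.asarray(x, dtype=float))
        return {k: np.asarray(ad.value_of(v)) for k, v in values.items()}

    def unconstrain(self, values: dict) -> np.ndarray:
        x = np.zeros(self.dim)
        for b in self.blocks:
            x[self.slices[b.name]] = np.atleast_1d(b.transform.inverse(values[b.name]))
        return x

    def block_names(self):
        return [b.name for b in self.blocks]

    def flat_labels(self):
        """One label per unconstrained coordinate, for traces."""
        labels = []
        for b in self.blocks:
            if b.size == 1:
                labels.append(b.name)
            else:
                labels.extend(f"{b.name}[{i}]" for i in range(b.size))
        return labels
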