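"""Bijective transforms between unconstrained vectors and constrained
model parameters, with log-Jacobians (the ADVI construction).

Each transform maps a slice of the global unconstrained vector to the
constrained domain and reports log|det J| of that map, so densities stated
on the constrained scale can be pulled back to the unconstrained one.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .tree import TimeTree, decode_heights, log_jacobian_heights


class Identity:
    """No-op transform for real-valued parameters."""

    def __init__(self, size: int):
        self.size = size

    def forward(self, y):
        return y, 0.0

    def inverse(self, x):
        return np.asarray(x, dtype=float)


class LogPositive:
    """x = exp(y); logJ = sum(y)."""

    def __init__(self, size: int = 1):
        self.size = size

    def forward(self, y):
        return ad.exp(y), ad.asum(y)

    def inverse(self, x):
        return np.log(np.asarray(x, dtype=float))


class LogisticUnit:
    """x = sigmoid(y) in (0,1); logJ = sum(log x + log(1-x))."""

    def __init__(self, size: int = 1):
        self.size = size

    def forward(self, y):
        x = ad.sigmoid(y)
        logj = ad.asum(ad.add(ad.log(x), ad.log(ad.sub(1.0, x))))
        return x, logj

    def inverse(self, x):
        x = np.asarray(x, dtype=float)
        return np.log(x) - np.log1p(-x)


class StickBreakingSimplex:
    """K-1 reals -> K-simplex (Stan's stick-breaking construction).

    The centering offset log(1/(K-k)) makes y = 0 map to the uniform
    simplex.
    """

    def __init__(self, k: int):
        if k < 2:
            raise ValueError("simplex needs K >= 2")
        self.k = k
        self.size = k - 1

    def forward(self, y):
        parts = []
        logj = 0.0
        remaining = 1.0
        for i in range(self.k - 1):
            z = ad.sigmoid(ad.sub(y[i], np.log(self.k - 1.0 - i)))
            xi = ad.mul(remaining, z)
            logj = ad.add(logj, ad.add(ad.log(z), ad.add(ad.log(ad.sub(1.0, z)),
                                                         ad.log(remaining))))
            parts.append(xi)
            remaining = ad.sub(remaining, xi)
        parts.append(remaining)
        return ad.stack(parts), logj

    def inverse(self, x):
        x = np.asarray(x, dtype=float)
        y = np.empty(self.k - 1)
        remaining = 1.0
        for i in range(self.k - 1):
            z = x[i] / remaining
            y[i] = np.log(z) - np.log1p(-z) + np.log(self.k - 1.0 - i)
            remaining -= x[i]
        return y


class HeightRatioTransform:
    """Unconstrained vector -> internal node heights of a fixed topology.

    Layout: slot 0 is log(root excess); slots 1..n-2 are logits of the
    per-node ratios (ordered as the tree's postorder minus the root).  The
    log-Jacobian combines the scalar transforms with the ratio-to-height
    factor sum log(h_parent - lb_i).
    """

    def __init__(self, tree: TimeTree):
        self.tree = tree
        self.size = tree.n_taxa - 1

    def forward(self, y):
        excess = ad.exp(y[0])
        logj = y[0]
        if self.size > 1:
            ratios = ad.sigmoid(y[1:])
            logj = ad.add(logj, ad.asum(ad.add(ad.log(ratios),
                                               ad.log(ad.sub(1.0, ratios)))))
        else:
            ratios = np.zeros(0)
        heights = decode_heights(self.tree, excess, ratios)
        logj = ad.add(logj, log_jacobian_heights(self.tree, heights))
        return heights, logj

    def inverse(self, heights):
        from .tree import heights_to_ratios
        r = heights_to_ratios(self.tree.with_heights(heights))
        y = np.empty(self.size)
        y[0] = np.log(r.root_excess)
        if self.size > 1:
            y[1:] = np.log(r.ratios) - np.log1p(-r.ratios)
        return y


TRANSFORMS = {
    "identity": Identity,
    "log_positive": LogPositive,
    "logistic_unit": LogisticUnit,
    "stick_breaking_simplex": StickBreakingSimplex,
    "height_ratios": HeightRatioTransform,
}
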