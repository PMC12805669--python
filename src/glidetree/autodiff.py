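"""Minimal reverse-mode automatic differentiation over numpy arrays.

The inference engines need gradients of the log joint density with respect
to the unconstrained parameter vector.  Rather than deriving every gradient
analytically, the model code is written once against a tiny tape-based
autodiff layer: a :class:`Tensor` wraps an ndarray and records the vector-
Jacobian product of every operation that produced it.  The dispatch helpers
(:func:`exp`, :func:`log`, :func:`asum`, ...) operate on plain arrays as
well, so the same model code evaluates cheaply without a tape when no
gradient is requested (this is what makes the forward-KL objective truly
gradient-free at the model level).

Only the operations the models need are implemented.  Matrix exponentials
(4x4 rate matrices) use scipy's Pade implementation with the adjoint of the
Frechet derivative as the reverse rule.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm as _scipy_expm, expm_frechet as _expm_frechet
from scipy.special import expit as _expit


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `shape`."""
    grad = np.asarray(grad, dtype=float)
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, n in enumerate(shape):
        if n == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Node in the computation tape.

    ``needs`` marks whether any differentiable leaf is upstream; constants
    (needs=False) terminate backward traversal.
    """

    __slots__ = ("value", "parents", "needs", "grad")

    def __init__(self, value, parents=(), needs=False):
        self.value = np.asarray(value, dtype=float)
        # parents: tuple of (parent_tensor, vjp_callable)
        self.parents = tuple(p for p in parents if p[0].needs)
        self.needs = needs or bool(self.parents)
        self.grad = None

    @staticmethod
    def param(value) -> "Tensor":
        t = Tensor(value)
        t.needs = True
        return t

    @property
    def shape(self):
        return self.value.shape

    def __float__(self):
        return float(self.value)

    # -- operator overloads ------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, expo):
        return power(self, expo)

    def __getitem__(self, idx):
        return getitem(self, idx)


def value_of(x):
    return x.value if isinstance(x, Tensor) else np.asarray(x, dtype=float)


def _is_t(*xs):
    return any(isinstance(x, Tensor) for x in xs)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- primitive operations --------------------------------------------------

def add(a, b):
    if not _is_t(a, b):
        return np.asarray(a, dtype=float) + np.asarray(b, dtype=float)
    a, b = _wrap(a), _wrap(b)
    out = a.value + b.value
    return Tensor(out, (
        (a, lambda g: _unbroadcast(g, a.value.shape)),
        (b, lambda g: _unbroadcast(g, b.value.shape)),
    ))


def sub(a, b):
    if not _is_t(a, b):
        return np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    a, b = _wrap(a), _wrap(b)
    return Tensor(a.value - b.value, (
        (a, lambda g: _unbroadcast(g, a.value.shape)),
        (b, lambda g: _unbroadcast(-g, b.value.shape)),
    ))


def mul(a, b):
    if not _is_t(a, b):
        return np.asarray(a, dtype=float) * np.asarray(b, dtype=float)
    a, b = _wrap(a), _wrap(b)
    av, bv = a.value, b.value
    return Tensor(av * bv, (
        (a, lambda g: _unbroadcast(g * bv, av.shape)),
        (b, lambda g: _unbroadcast(g * av, bv.shape)),
    ))


def div(a, b):
    if not _is_t(a, b):
        return np.asarray(a, dtype=float) / np.asarray(b, dtype=float)
    a, b = _wrap(a), _wrap(b)
    av, bv = a.value, b.value
    return Tensor(av / bv, (
        (a, lambda g: _unbroadcast(g / bv, av.shape)),
        (b, lambda g: _unbroadcast(-g * av / (bv * bv), bv.shape)),
    ))


def power(a, expo):
    """a**expo; the exponent may itself be differentiable if a > 0."""
    if _is_t(expo):
        return exp(mul(expo, log(a)))
    if not _is_t(a):
        return np.asarray(a, dtype=float) ** expo
    av = a.value
    out = av ** expo
    return Tensor(out, ((a, lambda g: _unbroadcast(g * expo * av ** (expo - 1), av.shape)),))


def exp(a):
    if not _is_t(a):
        return np.exp(np.asarray(a, dtype=float))
    out = np.exp(a.value)
    return Tensor(out, ((a, lambda g: g * out),))


def log(a):
    if not _is_t(a):
        return np.log(np.asarray(a, dtype=float))
    av = a.value
    return Tensor(np.log(av), ((a, lambda g: g / av),))


def sqrt(a):
    if not _is_t(a):
        return np.sqrt(np.asarray(a, dtype=float))
    out = np.sqrt(a.value)
    return Tensor(out, ((a, lambda g: g / (2.0 * out)),))


def absolute(a):
    if not _is_t(a):
        return np.abs(np.asarray(a, dtype=float))
    av = a.value
    return Tensor(np.abs(av), ((a, lambda g: g * np.sign(av)),))


def sigmoid(a):
    if not _is_t(a):
        return _expit(np.asarray(a, dtype=float))
    out = _expit(a.value)
    return Tensor(out, ((a, lambda g: g * out * (1.0 - out)),))


def asum(a, axis=None):
    if not _is_t(a):
        return np.sum(np.asarray(a, dtype=float), axis=axis)
    av = a.value
    out = np.sum(av, axis=axis)

    def vjp(g):
        if axis is None:
            return np.broadcast_to(g, av.shape).copy()
        return np.broadcast_to(np.expand_dims(g, axis), av.shape).copy()

    return Tensor(out, ((a, vjp),))


def getitem(a, idx):
    if not _is_t(a):
        return np.asarray(a, dtype=float)[idx]
    av = a.value
    out = av[idx]

    def vjp(g):
        full = np.zeros_like(av)
        np.add.at(full, idx, g)
        return full

    return Tensor(out, ((a, vjp),))


def reshape(a, shape):
    if not _is_t(a):
        return np.reshape(np.asarray(a, dtype=float), shape)
    av = a.value
    return Tensor(av.reshape(shape), ((a, lambda g: np.reshape(g, av.shape)),))


def stack(parts, axis=0):
    if not _is_t(*parts):
        return np.stack([np.asarray(p, dtype=float) for p in parts], axis=axis)
    parts = [_wrap(p) for p in parts]
    out = np.stack([p.value for p in parts], axis=axis)

    def make_vjp(i):
        return lambda g: np.take(g, i, axis=axis)

    return Tensor(out, tuple((p, make_vjp(i)) for i, p in enumerate(parts)))


def concatenate(parts, axis=0):
    if not _is_t(*parts):
        return np.concatenate([np.asarray(p, dtype=float) for p in parts], axis=axis)
    parts = [_wrap(p) for p in parts]
    out = np.concatenate([p.value for p in parts], axis=axis)
    offsets = np.cumsum([0] + [p.value.shape[axis] for p in parts])

    def make_vjp(i):
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(offsets[i], offsets[i + 1])
        sl = tuple(sl)
        return lambda g: g[sl]

    return Tensor(out, tuple((p, make_vjp(i)) for i, p in enumerate(parts)))


def einsum(subscripts, a, b):
    """Two-operand einsum.  Reverse rules swap the output subscript with the
    operand's; valid for contraction/broadcast patterns without diagonals."""
    if not _is_t(a, b):
        return np.einsum(subscripts, np.asarray(a, dtype=float), np.asarray(b, dtype=float))
    a, b = _wrap(a), _wrap(b)
    ins, out_sub = subscripts.split("->")
    sub_a, sub_b = ins.split(",")
    av, bv = a.value, b.value
    out = np.einsum(subscripts, av, bv)
    return Tensor(out, (
        (a, lambda g: np.einsum(f"{out_sub},{sub_b}->{sub_a}", g, bv)),
        (b, lambda g: np.einsum(f"{out_sub},{sub_a}->{sub_b}", g, av)),
    ))


def expm(a):
    """Matrix exponential of a small square matrix (Pade, scipy)."""
    if not _is_t(a):
        return _scipy_expm(np.asarray(a, dtype=float))
    av = a.value

    def vjp(g):
        # adjoint of the Frechet derivative: L*(A)[G] = L(A^T)[G]
        return _expm_frechet(av.T, g, compute_expm=False)

    return Tensor(_scipy_expm(av), ((a, vjp),))


def logsumexp(a, axis=None):
    m = np.max(value_of(a), axis=axis, keepdims=True)
    shifted = sub(a, m) if _is_t(a) else a - m
    s = log(asum(exp(shifted), axis=axis))
    return add(s, np.squeeze(m, axis=axis) if axis is not None else m.reshape(()))


def custom_primitive(value, inputs_and_vjps):
    """Build a Tensor from a precomputed value with explicit reverse rules.

    `inputs_and_vjps` is a sequence of (Tensor, vjp) pairs; used for
    operations whose derivative is supplied externally (e.g. finite
    differences for gamma quantiles)."""
    return Tensor(value, tuple(inputs_and_vjps))


# -- backward pass ---------------------------------------------------------

def _toposort(root: Tensor):
    order, seen, stack = [], set(), [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for parent, _ in node.parents:
            if id(parent) not in seen:
                stack.append((parent, False))
    return order  # DFS postorder: producers before the nodes consuming them


def grad(output: Tensor, inputs) -> list:
    """Gradient of a scalar `output` with respect to each Tensor in `inputs`."""
    if output.value.shape != ():
        raise ValueError("grad requires a scalar output")
    order = _toposort(output)
    wanted = {id(t): t for t in inputs}
    grads = {id(output): np.ones(())}
    saved = {}
    # reverse postorder visits every consumer before its producers, so each
    # node's adjoint is complete when popped
    for node in reversed(order):
        g = grads.pop(id(node), None)
        if g is None:
            continue
        if id(node) in wanted:
            saved[id(node)] = g
        for parent, vjp in node.parents:
            contrib = np.asarray(vjp(g), dtype=float)
            key = id(parent)
            if key in grads:
                grads[key] = grads[key] + contrib
            else:
                grads[key] = contrib
    return [saved.get(id(t), np.zeros(t.value.shape)) for t in inputs]
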