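"""Inference engines: variational inference (ELBO or forward-KL/SNIS
objectives, mean-field or full-rank Gaussian families), Hamiltonian Monte
Carlo, and MAP optimization.  All operate on the unconstrained space of a
:class:`~glidetree.posterior.JointPosterior`.

The two variational objectives differ in what they ask of the model:

* ELBO (reverse KL, mode-seeking): pathwise gradients through z = mu +
  sigma * eps require the gradient of the log joint.
* forward KL (mass-covering): the self-normalized importance-sampling
  estimator needs only *evaluations* of the log joint; gradients are taken
  of log q alone.  This is why it tolerates discontinuous models such as
  the piecewise-constant skygrid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from . import autodiff as ad
from .posterior import JointPosterior, NumericError

LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# variational families
# ---------------------------------------------------------------------------

class MeanFieldGaussian:
    """Fully factorized Gaussian on the unconstrained space."""

    def __init__(self, mu, log_sigma):
        self.mu = np.asarray(mu, dtype=float)
        self.log_sigma = np.asarray(log_sigma, dtype=float)
        if self.mu.shape != self.log_sigma.shape:
            raise ValueError("mu and log_sigma must have the same length")

    @classmethod
    def initial(cls, dim, mu=None, sigma=0.1):
        m = np.zeros(dim) if mu is None else np.asarray(mu, dtype=float)
        return cls(m, np.full(dim, np.log(sigma)))

    @property
    def dim(self):
        return len(self.mu)

    @property
    def sigma(self):
        return np.exp(self.log_sigma)

    def get_phi(self):
        return np.concatenate([self.mu, self.log_sigma])

    def set_phi(self, phi):
        d = self.dim
        self.mu = phi[:d].copy()
        self.log_sigma = phi[d:].copy()

    def sample(self, rng, n):
        eps = rng.standard_normal((n, self.dim))
        return self.mu + self.sigma * eps

    def log_density(self, z):
        z = np.atleast_2d(z)
        w = (z - self.mu) / self.sigma
        return (-0.5 * np.sum(w * w, axis=1)
                - np.sum(self.log_sigma) - 0.5 * self.dim * LOG_2PI)

    # -- autodiff pieces ---------------------------------------------------
    def phi_params(self):
        return [ad.Tensor.param(self.mu), ad.Tensor.param(self.log_sigma)]

    def z_expr(self, params, eps):
        mu_t, ls_t = params
        return ad.add(mu_t, ad.mul(ad.exp(ls_t), eps))

    def logq_expr(self, params, z):
        mu_t, ls_t = params
        w = ad.div(ad.sub(z, mu_t), ad.exp(ls_t))
        return ad.sub(ad.mul(-0.5, ad.asum(ad.mul(w, w))),
                      ad.add(ad.asum(ls_t), 0.5 * self.dim * LOG_2PI))

    def entropy_expr(self, params):
        _, ls_t = params
        return ad.add(ad.asum(ls_t), 0.5 * self.dim * (LOG_2PI + 1.0))

    def copy(self):
        return MeanFieldGaussian(self.mu.copy(), self.log_sigma.copy())


class FullRankGaussian:
    """Multivariate Gaussian with Cholesky-parameterized covariance.

    phi layout: mu (d), then the lower triangle of L packed row-wise with
    the diagonal stored on the log scale.
    """

    def __init__(self, mu, packed_l):
        self.mu = np.asarray(mu, dtype=float)
        d = len(self.mu)
        if len(packed_l) != d * (d + 1) // 2:
            raise ValueError("packed Cholesky factor has wrong length")
        self.packed_l = np.asarray(packed_l, dtype=float)

    @classmethod
    def from_mean_field(cls, mf: MeanFieldGaussian):
        """Initialize at a mean-field optimum with zero off-diagonal
        covariances (the stable way to start a full-rank fit)."""
        d = mf.dim
        packed = []
        for i in range(d):
            packed.extend([0.0] * i)
            packed.append(mf.log_sigma[i])
        return cls(mf.mu.copy(), np.array(packed))

    @property
    def dim(self):
        return len(self.mu)

    def cholesky(self):
        d = self.dim
        L = np.zeros((d, d))
        k = 0
        for i in range(d):
            L[i, :i] = self.packed_l[k:k + i]
            L[i, i] = np.exp(self.packed_l[k + i])
            k += i + 1
        return L

    def get_phi(self):
        return np.concatenate([self.mu, self.packed_l])

    def set_phi(self, phi):
        d = self.dim
        self.mu = phi[:d].copy()
        self.packed_l = phi[d:].copy()

    def sample(self, rng, n):
        eps = rng.standard_normal((n, self.dim))
        return self.mu + eps @ self.cholesky().T

    def log_density(self, z):
        z = np.atleast_2d(z)
        L = self.cholesky()
        w = np.linalg.solve(L, (z - self.mu).T).T
        return (-0.5 * np.sum(w * w, axis=1)
                - np.sum(np.log(np.diag(L))) - 0.5 * self.dim * LOG_2PI)

    # -- autodiff pieces ---------------------------------------------------
    def phi_params(self):
        return [ad.Tensor.param(self.mu), ad.Tensor.param(self.packed_l)]

    def _l_rows(self, packed_t):
        d = self.dim
        rows, k = [], 0
        for i in range(d):
            off = packed_t[k:k + i] if i else None
            diag = ad.exp(packed_t[k + i])
            parts = []
            if off is not None:
                parts.append(off)
            parts.append(ad.reshape(diag, (1,)))
            if i < d - 1:
                parts.append(np.zeros(d - 1 - i))
            rows.append(ad.concatenate(parts))
            k += i + 1
        return rows

    def z_expr(self, params, eps):
        mu_t, packed_t = params
        rows = self._l_rows(packed_t)
        L = ad.stack(rows)
        return ad.add(mu_t, ad.einsum("ij,j->i", L, eps))

    def logq_expr(self, params, z):
        mu_t, packed_t = params
        rows = self._l_rows(packed_t)
        r = ad.sub(z, mu_t)
        d = self.dim
        # forward substitution L w = r in the graph
        w = []
        log_diag_sum = 0.0
        k = 0
        for i in range(d):
            acc = r[i]
            if i:
                acc = ad.sub(acc, ad.asum(ad.mul(rows[i][:i], ad.stack(w))))
            diag = ad.exp(packed_t[k + i])
            w.append(ad.div(acc, diag))
            log_diag_sum = ad.add(log_diag_sum, packed_t[k + i])
            k += i + 1
        wv = ad.stack(w)
        return ad.sub(ad.mul(-0.5, ad.asum(ad.mul(wv, wv))),
                      ad.add(log_diag_sum, 0.5 * d * LOG_2PI))

    def entropy_expr(self, params):
        _, packed_t = params
        d = self.dim
        k, total = 0, 0.0
        for i in range(d):
            total = ad.add(total, packed_t[k + i])
            k += i + 1
        return ad.add(total, 0.5 * d * (LOG_2PI + 1.0))

    def copy(self):
        return FullRankGaussian(self.mu.copy(), self.packed_l.copy())


# ---------------------------------------------------------------------------
# ELBO
# ---------------------------------------------------------------------------

def elbo_estimate(q, model: JointPosterior, n_samples: int, rng) -> float:
    """Monte-Carlo ELBO: mean of log p(z, D) - log q(z) over q-samples."""
    z = q.sample(rng, n_samples)
    lq = q.log_density(z)
    vals = [model.log_joint(z[s]) - lq[s] for s in range(n_samples)]
    return float(np.mean(vals))


def elbo_value_and_grad(q, model: JointPosterior, n_samples: int, rng,
                        entropy: str = "monte_carlo"):
    """Pathwise (reparameterization) ELBO gradient with respect to phi.

    entropy='monte_carlo' uses -log q(z) inside the estimator (the exact
    single-sample ELBO); entropy='analytic' swaps in the closed-form
    Gaussian entropy, trading a little bias structure for lower variance.
    """
    params = q.phi_params()
    eps = rng.standard_normal((n_samples, q.dim))
    total = 0.0
    for s in range(n_samples):
        z = q.z_expr(params, eps[s])
        lp = model._expr(z)
        if entropy == "analytic":
            term = lp
        else:
            term = ad.sub(lp, q.logq_expr(params, z))
        total = ad.add(total, term)
    total = ad.div(total, float(n_samples))
    if entropy == "analytic":
        total = ad.add(total, q.entropy_expr(params))
    grads = ad.grad(total, params)
    return float(total.value), np.concatenate([g.ravel() for g in grads])


# ---------------------------------------------------------------------------
# forward KL via self-normalized importance sampling
# ---------------------------------------------------------------------------

@dataclass
class SNISBatch:
    """Samples from q with self-normalized importance weights against the
    unnormalized posterior."""

    samples: np.ndarray
    log_ratios: np.ndarray      # log p~(z) - log q(z), unnormalized
    weights: np.ndarray
    ess: float
    kl_report: float


class DegenerateBatchError(RuntimeError):
    pass


def snis_batch(q, model: JointPosterior, n_samples: int, rng) -> SNISBatch:
    """Draw S samples from q and self-normalize the importance ratios.

    The KL report is the SNIS estimate of KL(p||q): sum_s w_s (log p~_s -
    log q_s) minus the log of the normalizing-constant estimate
    (1/S) sum exp(log ratios).
    """
    if n_samples < 2:
        raise ValueError("SNIS needs at least two samples")
    z = q.sample(rng, n_samples)
    lq = q.log_density(z)
    lp = np.empty(n_samples)
    for s in range(n_samples):
        try:
            lp[s] = model.log_joint(z[s])
        except NumericError:
            lp[s] = -np.inf
    lr = lp - lq
    if not np.any(np.isfinite(lr)):
        raise DegenerateBatchError("all importance ratios are degenerate")
    shift = np.max(lr)
    raw = np.exp(lr - shift)
    w = raw / raw.sum()
    log_norm = shift + np.log(raw.sum() / n_samples)
    finite = np.isfinite(lr)
    kl = float(np.sum(w[finite] * lr[finite]) - log_norm)
    ess = float(1.0 / np.sum(w * w))
    return SNISBatch(z, lr, w, ess, kl)


def forward_kl_gradient(batch: SNISBatch, q) -> np.ndarray:
    """Gradient of the SNIS cross-entropy objective
    L_KL(phi) = -sum_s w_s log q(z~_s; phi)
    with samples and weights held constant (no gradient flows through z~ or
    w), so the model itself is never differentiated."""
    params = q.phi_params()
    total = 0.0
    for s in range(len(batch.weights)):
        if batch.weights[s] == 0.0:
            continue
        total = ad.add(total, ad.mul(batch.weights[s],
                                     q.logq_expr(params, batch.samples[s])))
    total = ad.mul(total, -1.0)
    grads = ad.grad(total, params)
    return np.concatenate([g.ravel() for g in grads])


# ---------------------------------------------------------------------------
# optimization loop
# ---------------------------------------------------------------------------

class Adam:
    """Adam with 1/sqrt(t) step-size decay (decay can be disabled)."""

    def __init__(self, dim, lr=0.1, beta1=0.9, beta2=0.999, eps=1e-8,
                 decay=True, decay_t0=100.0):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.decay, self.decay_t0 = decay, decay_t0
        self.m = np.zeros(dim)
        self.v = np.zeros(dim)
        self.t = 0

    def step(self, phi, grad):
        """One minimization step; pass the gradient of the loss."""
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * grad
        self.v = self.beta2 * self.v + (1 - self.beta2) * grad * grad
        mhat = self.m / (1 - self.beta1 ** self.t)
        vhat = self.v / (1 - self.beta2 ** self.t)
        lr = self.lr
        if self.decay:
            lr = self.lr / np.sqrt(1.0 + self.t / self.decay_t0)
        return phi - lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class VITrace:
    iterations: list = field(default_factory=list)
    objective: list = field(default_factory=list)
    mu: list = field(default_factory=list)         # per-checkpoint copies
    sigma2: list = field(default_factory=list)
    objective_name: str = "elbo"


def fit_vi(model: JointPosterior, objective="elbo", family="mean_field",
           iterations=2000, learning_rate=None, samples_per_step=None,
           seed=0, rng=None, init_mu=None, init_sigma=0.1,
           init_family=None, checkpoint_every=None, entropy="monte_carlo",
           lr_decay=True, average_fraction=0.25):
    """Run the VI optimization loop; returns (fitted family, VITrace).

    Defaults follow the study setup: ELBO uses one sample per step and
    learning rate 0.1 for mean-field (1e-5 for full-rank); forward KL uses
    the 10-sample SNIS estimator.  ``init_family`` supports initializing a
    full-rank fit from an optimized mean-field one.  The returned family
    carries the Polyak average of the final ``average_fraction`` of
    iterates (set 0 to disable), which removes the stationary jitter of
    the stochastic optimizer.  Deterministic given the seed.
    """
    if objective not in ("elbo", "forward_kl"):
        raise ValueError(f"unknown objective {objective!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    if samples_per_step is None:
        samples_per_step = 1 if objective == "elbo" else 10
    if learning_rate is None:
        learning_rate = 1e-5 if family == "full_rank" else 0.1

    if init_family is not None:
        if family == "full_rank" and isinstance(init_family, MeanFieldGaussian):
            q = FullRankGaussian.from_mean_field(init_family)
        else:
            q = init_family.copy()
    elif family == "mean_field":
        q = MeanFieldGaussian.initial(model.dim, mu=init_mu, sigma=init_sigma)
    elif family == "full_rank":
        mf = MeanFieldGaussian.initial(model.dim, mu=init_mu, sigma=init_sigma)
        q = FullRankGaussian.from_mean_field(mf)
    else:
        raise ValueError(f"unknown family {family!r}")

    if checkpoint_every is None:
        checkpoint_every = max(1, min(1000, iterations // 20))

    phi = q.get_phi()
    opt = Adam(len(phi), lr=learning_rate, decay=lr_decay)
    trace = VITrace(objective_name=objective)
    avg_start = iterations - int(np.floor(average_fraction * iterations)) + 1
    phi_sum = np.zeros_like(phi)
    phi_count = 0

    for it in range(1, iterations + 1):
        q.set_phi(phi)
        try:
            if objective == "elbo":
                value, g = elbo_value_and_grad(q, model, samples_per_step, rng,
                                               entropy=entropy)
                loss_grad = -g
            else:
                batch = snis_batch(q, model, samples_per_step, rng)
                value = batch.kl_report
                loss_grad = forward_kl_gradient(batch, q)
        except (NumericError, DegenerateBatchError) as err:
            raise NumericError(f"objective failed at iteration {it}: {err}")
        phi = opt.step(phi, loss_grad)
        if it >= avg_start:
            phi_sum += phi
            phi_count += 1
        if it % checkpoint_every == 0 or it == iterations:
            q.set_phi(phi)
            trace.iterations.append(it)
            trace.objective.append(value)
            if isinstance(q, MeanFieldGaussian):
                trace.mu.append(q.mu.copy())
                trace.sigma2.append(q.sigma ** 2)
            else:
                L = q.cholesky()
                trace.mu.append(q.mu.copy())
                trace.sigma2.append(np.sum(L * L, axis=1))
    q.set_phi(phi_sum / phi_count if phi_count else phi)
    return q, trace


# ---------------------------------------------------------------------------
# Hamiltonian Monte Carlo
# ---------------------------------------------------------------------------

@dataclass
class HMCResult:
    samples: np.ndarray           # post-warmup, unconstrained
    accept_rate: float
    step_size: float
    mass_diag: np.ndarray
    divergences: int


def leapfrog(grad_fn, z, p, step, n_steps, mass_diag):
    """Standard leapfrog integration of Hamiltonian dynamics."""
    z, p = z.copy(), p.copy()
    _, g = grad_fn(z)
    for _ in range(n_steps):
        p = p + 0.5 * step * g
        z = z + step * p / mass_diag
        _, g = grad_fn(z)
        p = p + 0.5 * step * g
    return z, p


def hmc_sample(model: JointPosterior, n_samples=1000, warmup=500,
               n_leapfrog=10, target_accept=0.8, seed=0, rng=None,
               init=None, max_energy_error=1000.0) -> HMCResult:
    """HMC with dual-averaging step-size adaptation and a diagonal mass
    matrix estimated from warmup draws (two warmup windows: unit mass,
    then re-adaptation under the estimated mass)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    z = np.zeros(model.dim) if init is None else np.asarray(init, dtype=float)

    def grad_fn(x):
        return model.log_joint_grad(x)

    def logp(x):
        try:
            return model.log_joint(x)
        except NumericError:
            return -np.inf

    mass = np.ones(model.dim)
    step = 0.1
    divergences = 0

    # dual averaging state (Hoffman & Gelman scheme)
    def make_da(step0):
        return {"mu": np.log(10 * step0), "log_step_bar": 0.0, "h_bar": 0.0,
                "gamma": 0.05, "t0": 10.0, "kappa": 0.75, "t": 0}

    def da_update(state, accept_prob):
        state["t"] += 1
        t = state["t"]
        eta = 1.0 / (t + state["t0"])
        state["h_bar"] = (1 - eta) * state["h_bar"] + eta * (target_accept - accept_prob)
        log_step = state["mu"] - np.sqrt(t) / state["gamma"] * state["h_bar"]
        w = t ** (-state["kappa"])
        state["log_step_bar"] = w * log_step + (1 - w) * state["log_step_bar"]
        return float(np.exp(log_step))

    def one_transition(z, step, mass):
        nonlocal divergences
        # trajectory length jittered to break resonances
        n_steps = int(rng.integers(1, n_leapfrog + 1))
        p = rng.standard_normal(model.dim) * np.sqrt(mass)
        h0 = -logp(z) + 0.5 * np.sum(p * p / mass)
        try:
            z_new, p_new = leapfrog(grad_fn, z, p, step, n_steps, mass)
            h1 = -logp(z_new) + 0.5 * np.sum(p_new * p_new / mass)
            d_h = h1 - h0
        except NumericError:
            d_h = np.inf
        if not np.isfinite(d_h) or d_h > max_energy_error:
            divergences += 1
            return z, 0.0
        accept_prob = min(1.0, float(np.exp(-d_h)))
        if rng.uniform() < accept_prob:
            return z_new, accept_prob
        return z, accept_prob

    # three warmup phases: step adaptation under unit mass; mass-estimation
    # window; step re-adaptation under the estimated mass.  The variance
    # estimate is shrunk toward 1 (Stan-style regularization) so a poorly
    # mixed window cannot freeze a coordinate.
    p1 = warmup // 4
    p2 = warmup // 2
    da = make_da(step)
    for _ in range(p1):
        z, aprob = one_transition(z, step, mass)
        step = da_update(da, aprob)
    step = float(np.exp(da["log_step_bar"])) if p1 else step
    window = []
    for _ in range(p2):
        z, aprob = one_transition(z, step, mass)
        window.append(z.copy())
    if window:
        draws = np.array(window)
        n_w = len(draws)
        var = (n_w * np.var(draws, axis=0) + 5.0) / (n_w + 5.0)
        mass = 1.0 / np.clip(var, 1e-6, None)
    da = make_da(max(step, 1e-8))
    for _ in range(warmup - p1 - p2):
        z, aprob = one_transition(z, step, mass)
        step = da_update(da, aprob)
    step = float(np.exp(da["log_step_bar"])) if warmup else step

    samples = np.empty((n_samples, model.dim))
    accepted = 0.0
    for i in range(n_samples):
        z, aprob = one_transition(z, step, mass)
        accepted += aprob
        samples[i] = z
    return HMCResult(samples, accepted / max(n_samples, 1), step, mass, divergences)


def constrained_samples(model: JointPosterior, samples: np.ndarray) -> dict:
    """Map unconstrained draws through the block transforms."""
    out = {b.name: [] for b in model.blocks}
    for row in samples:
        values = model.constrain(row)
        for k, v in values.items():
            out[k].append(v)
    return {k: np.array(v) for k, v in out.items()}


# ---------------------------------------------------------------------------
# MAP
# ---------------------------------------------------------------------------

@dataclass
class MAPResult:
    x: np.ndarray
    values: dict
    log_joint: float
    grad_norm: float
    converged: bool


def map_optimize(model: JointPosterior, x0=None, maxiter=1000) -> MAPResult:
    """Maximize the log joint over the unconstrained vector (L-BFGS)."""
    x0 = np.zeros(model.dim) if x0 is None else np.asarray(x0, dtype=float)

    def objective(x):
        try:
            v, g = model.log_joint_grad(x)
        except NumericError:
            return np.inf, np.zeros_like(x)
        return -v, -g

    res = _scipy_minimize(objective, x0, jac=True, method="L-BFGS-B",
                          options={"maxiter": maxiter})
    v, g = model.log_joint_grad(res.x)
    return MAPResult(res.x, model.constrain(res.x), v,
                     float(np.linalg.norm(g)), bool(res.success))
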