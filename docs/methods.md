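# Methods

This note records the modeling assumptions, parameter conventions,
numerical choices and known limitations of glidetree, in the spirit of a
software methods appendix.

## Time trees and the height-ratio reparameterization

Time is measured as *height*: years before the most recent sample; the
youngest tip sits at height 0. The topology is fixed for an entire
analysis. Internal node heights are the only tree parameters, and they are
reparameterized for unconstrained optimization: each non-root internal
node $i$ with parent height $h_p$ and lower bound $\ell_i$ (the maximum
descendant tip height, computed once since the topology never changes)
carries the ratio $r_i = (h_i - \ell_i)/(h_p - \ell_i) \in (0,1)$; the
root carries its excess $h_\text{root} - \ell_\text{root} > 0$. Ratios are
logit-transformed and the excess log-transformed on the unconstrained
vector. The decode is a preorder recursion and the log-Jacobian of
heights with respect to ratios is $\sum_i \log(h_p - \ell_i)$; we add this
pull-back term to the log joint (the density is stated on heights, the
parameters are ratios). At equal event heights, sampling events are
processed before coalescences, which keeps the lineage count at least two
at every coalescence.

Calendar dates exist only at the I/O boundary. Tip dates may be embedded
in labels (`name_YYYY`, split at the last underscore) or given as a TSV
table; the table wins on conflict. With dates, tip heights are
$\max(\text{date}) - \text{date}$ and internal heights are anchored by the
branch lengths; inputs are assumed internally consistent.

## Substitution, site and clock models

Rate matrices are built as $q_{ij} = b_{ij}\, \pi_j\, e^{\varepsilon_{ij}}$
(JC69: $b \equiv 1$; HKY: $b = \kappa$ on transitions; GTR: six symmetric
exchange parameters modeled as a simplex, the scale being absorbed by the
normalization) and normalized so $-\sum_i \pi_i q_{ii} = 1$ *after* the
random effects are applied — the effects therefore change relative rather
than absolute rates, and the clock rate stays identifiable. Frequencies
are free simplex parameters with a flat Dirichlet prior. Twelve ordered
pair effects $\varepsilon$ make the process nonreversible; their prior is
the original Bayesian bridge
$p(\varepsilon \mid \tau_b, \alpha) = \frac{\alpha}{2\tau_b\Gamma(1/\alpha)}
e^{-|\varepsilon/\tau_b|^\alpha}$ with $\alpha = 0.25$ and a
Gamma(shape 1, scale 2) hyperprior on $\nu = \tau_b^{-\alpha}$, the
parameterization in which that hyperprior is stated.

Transition probabilities: plain evaluation uses the symmetric
eigendecomposition of $D_\pi^{1/2} Q D_\pi^{-1/2}$ for reversible models
and the dense Padé matrix exponential for the random-effects model. The
differentiable path uses the Padé exponential for *all* models, with the
adjoint of the Fréchet derivative as the reverse rule — eigendecomposition
backprop is ill-defined at repeated eigenvalues, which JC69 and HKY have.
JC69 additionally has a closed-form $P(t)$ used as a vectorized fast path.

Site-rate heterogeneity uses quantile-midpoint ("median") discretization
of a mean-one Weibull or gamma with $K$ equal-weight categories, re
normalized so the category mean is exactly 1. The Weibull inverse CDF is
closed-form and differentiates analytically (the unit-mean scale cancels
in the renormalization); the gamma inverse CDF has no convenient shape
derivative, so its reverse rule uses central finite differences (step
$10^{-6}\max(1, a)$), the same device used by production AD phylogenetics
backends for this model.

The clock is strict; a fixed rate (as in the isochronous study setup,
7.9e-4 subst/site/year) is excluded from the parameter vector entirely.

## Coalescent models

Both grid models place $M+1$ log population sizes $\gamma_i$ at
equidistant times $0 = x_0 < \dots < x_M = C$ and extend $\theta_M$ beyond
the cutoff. The skygrid holds $N(t)$ constant per cell (jump
discontinuities at cell boundaries); the skyglide interpolates linearly
(continuous, though not differentiable at the grid times). The
heterochronous density sums $-\binom{k}{2}\int 1/N$ over inter-event
intervals plus $\log\binom{k}{2} - \log N(t_c)$ at each coalescence;
sampling events contribute no point mass. Within a linear cell the
integral is $(\log N(v) - \log N(u))/b$ for slope $b$; cells with
$|b| < 10^{-12}\,\theta_i$ fall back to the constant form to avoid
catastrophic cancellation. Segment-to-cell assignment uses the segment
midpoint, which is robust to floating-point jitter when an endpoint sits
exactly on a grid time. The hot path used inside the joint posterior is a
vectorized evaluation of the cumulative inverse-population integral at all
event heights (detached cell indices and masks, differentiable values);
it is tested to agree with the composition of the scalar primitives to
1e-10.

The smoothing prior on $\gamma$ is an intrinsic GMRF on adjacent
differences, $(M/2)\log(\kappa/2\pi) - (\kappa/2)\sum(\Delta\gamma)^2$ —
normalized in $\kappa$, shift-invariant in level (the level is informed by
the coalescent likelihood). The hyperprior on $\kappa$ is Gamma(0.005,
rate 0.005), the conventional skygrid choice; both hyperparameters are
configurable because the shape/rate-vs-scale convention is ambiguous in
parts of the literature.

## Autodiff

Gradients of the log joint come from a small tape-based reverse-mode
autodiff layer over numpy (`glidetree.autodiff`). Model code is written
once against dispatch helpers that operate on plain arrays as well, so a
gradient-free evaluation builds no tape at all — this is what makes the
forward-KL objective genuinely gradient-free at the model level, which a
call-counting test enforces. The operation set is exactly what the models
need (elementwise arithmetic, reductions, indexing, two-operand einsum,
matrix exponential); gradients are verified against central finite
differences at relative tolerance 1e-4 throughout the test suite.

## Inference engines

**Variational families.** Mean-field: independent Gaussians on the
unconstrained scale. Full-rank: Cholesky-parameterized covariance with
log-diagonal; it can be initialized from a fitted mean-field approximation
with zero off-diagonals (the stabilization used in the full-scale
analyses; the full-rank default learning rate is 1e-5 against the
mean-field 0.1).

**ELBO.** Single-sample pathwise estimator by default,
$z = \mu + \sigma \odot \epsilon$; the Monte-Carlo entropy form
($-\log q(z)$ inside the estimator) is the default so the same estimator
serves both families, with the analytic-entropy variant available.

**Forward KL.** Fresh SNIS batches of $S = 10$ samples from the current
$q$ per step; weights $w_s \propto \tilde p(z_s)/q(z_s)$ computed with a
single max-shift in log space; the gradient is
$-\sum_s w_s \nabla_\phi \log q(\tilde z_s;\phi)$ with samples and weights
held constant. The KL report subtracts the log normalizing-constant
estimate. The estimator is asymptotically unbiased but can be slow when
$q$ is far from $p$ (weight degeneracy), which motivates the warm start
below.

**Optimizer.** Adam with learning-rate decay $\eta_t =
\eta_0/\sqrt{1 + t/100}$ and Polyak averaging of the final 25% of iterates
(50% on the calibration toys) — the averaged iterate removes the
stationary jitter of the stochastic gradient, which otherwise dominates
the error at desk-scale iteration counts. The phylodynamic fits
warm-start the variational mean at the MAP optimum with initial
$\sigma = 0.05$; this plays the role of the long optimization runs of the
full-scale analyses and keeps SNIS weights non-degenerate from the first
step. Runs are deterministic given the seed.

**HMC.** Leapfrog with a trajectory length jittered uniformly in
$\{1,\dots,10\}$ steps (a fixed length resonates on near-Gaussian
targets), Metropolis correction, dual-averaging step-size adaptation to
target acceptance 0.8, and a diagonal mass matrix estimated from a middle
warmup window with Stan-style shrinkage toward unit mass. Energy errors
above 1000 count as divergences and are rejected.

**MAP.** L-BFGS on the unconstrained vector; note this maximizes the
*pulled-back* density including Jacobian terms, which is the mode of the
unconstrained, not the constrained, density — the conjugate-toy test uses
an identity transform where the two coincide.

## Synthetic data

The simulators provide every dataset used in testing. Coalescent trees
are drawn by time-rescaling (analytic inversion for constant and
exponential demographies, bisection to 1e-10 years for piecewise ones);
sequences evolve from a stationary root state with per-branch,
per-category transition matrices. Scenario presets mirror the two
empirical setups at toy scale — `hcv_like` (isochronous, GTR+Γ₄, clock
fixed at 7.9e-4, 8-segment grid) and `sc2_like` (heterochronous, HKY with
random effects under the bridge prior with $\alpha = 0.25$, 5-segment
skyglide, cutoff 0.3) — plus the three demographic validation scenarios
(constant N = 5, exponential growth, bottleneck).

The sharp-change experiment (`glidetree.experiments`) uses 16 tips sampled
over 3 years, N dropping from 5 to 0.5 at height 4, 200 JC69 sites, clock
0.02, and a 6-segment grid with cutoff 8 — sizes chosen so a replicate
fits in about a minute while the posterior still constrains the root
height. What the generator does *not* emulate: rate variation across
lineages, alignment error, recombination, selection, population structure,
and topology uncertainty. Passing tests therefore certify the inference
machinery against its own generative model, not robustness to real-data
violations of it.

## Problem sizes and defaults used in the shipped checks

Calibration toys run 20 000 ELBO / 8 000 forward-KL iterations (the
single-sample ELBO gradient is the noisier of the two). Phylodynamic fits
use 1 500–2 500 iterations from the MAP warm start, 16–20 taxa, 200–300
sites and 6–8 grid segments. The SNIS calibration uses a Gaussian pair
with bounded importance ratios ($p = N(0.5, 0.8^2)$ against
$q = N(0, 1.2^2)$) at $S = 10^5$; with $q$ narrower than $p$ the
estimator's documented weight degeneracy would dominate instead.

## Known limitations

Mean-field VI underestimates posterior spread; the forward-KL objective
does not reliably fix this at practical sample sizes (a known property of
SNIS gradients in high dimensions). The forward-KL arm needs a reasonable
initialization to avoid weight collapse. Topology is never inferred, and
fixing it understates all uncertainties. The autodiff layer is
deliberately minimal: graphs are built per evaluation in Python, which is
the dominant cost at scale; analytic-gradient backends are out of scope.
Only nucleotide models, the strict clock, and the three coalescent
families described above are implemented.
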