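"""Variational objectives, SNIS, the optimization loop, HMC, and MAP."""

import numpy as np
import pytest

from glidetree.alignment import Alignment
from glidetree import autodiff as ad
from glidetree.inference import (Adam, DegenerateBatchError, FullRankGaussian,
                                 MeanFieldGaussian, elbo_estimate,
                                 elbo_value_and_grad, fit_vi,
                                 forward_kl_gradient, hmc_sample, leapfrog,
                                 map_optimize, snis_batch)
from glidetree.likelihood import pruning_log_likelihood
from glidetree.posterior import JointPosterior, ParameterBlock
from glidetree.toys import ConjugateNormal, gaussian_model, mixture_model, \
    standard_normal_model
from glidetree.transforms import Identity
from glidetree.tree import TimeTree


@pytest.fixture
def conjugate():
    return ConjugateNormal(0.0, 2.0, np.array([1.2, 0.8, 1.5, 0.9]), 1.0)


class TestELBOEstimator:
    def test_zero_kl_has_zero_mean(self):
        model = standard_normal_model(1)
        q = MeanFieldGaussian(np.zeros(1), np.zeros(1))
        rng = np.random.default_rng(0)
        vals = [elbo_estimate(q, model, 1, rng) for _ in range(10_000)]
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se + 1e-12

    def test_matches_closed_form_gaussian_kl(self):
        # target N(0,1), q = N(m, s): ELBO = -KL = -(-log s + (s^2+m^2-1)/2)
        m, s = 0.7, 1.4
        model = standard_normal_model(1)
        q = MeanFieldGaussian(np.array([m]), np.array([np.log(s)]))
        rng = np.random.default_rng(1)
        vals = [elbo_estimate(q, model, 1, rng) for _ in range(20_000)]
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        expected = -(-np.log(s) + (s ** 2 + m ** 2 - 1) / 2)
        assert abs(np.mean(vals) - expected) < 3 * se

    def test_exact_posterior_elbo_is_log_evidence(self, conjugate):
        model = conjugate.model()
        q = MeanFieldGaussian(np.array([conjugate.posterior_mean]),
                              np.array([np.log(conjugate.posterior_sd)]))
        rng = np.random.default_rng(2)
        vals = [elbo_estimate(q, model, 1, rng) for _ in range(5_000)]
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        # when q is exactly the posterior every sample equals the evidence
        assert abs(np.mean(vals) - conjugate.log_evidence) < 3 * se + 1e-9

    def test_elbo_never_exceeds_evidence(self, conjugate):
        model = conjugate.model()
        rng = np.random.default_rng(3)
        for m, ls in [(0.0, 0.0), (1.0, -0.5), (2.0, 0.3)]:
            q = MeanFieldGaussian(np.array([m]), np.array([ls]))
            vals = [elbo_estimate(q, model, 1, rng) for _ in range(3_000)]
            se = np.std(vals, ddof=1) / np.sqrt(len(vals))
            assert np.mean(vals) <= conjugate.log_evidence + 3 * se


class TestELBOGradient:
    def test_zero_expectation_at_exact_posterior(self, conjugate):
        model = conjugate.model()
        q = MeanFieldGaussian(np.array([conjugate.posterior_mean]),
                              np.array([np.log(conjugate.posterior_sd)]))
        rng = np.random.default_rng(4)
        grads = np.array([elbo_value_and_grad(q, model, 1, rng)[1]
                          for _ in range(10_000)])
        se = grads.std(axis=0, ddof=1) / np.sqrt(len(grads))
        assert np.all(np.abs(grads.mean(axis=0)) < 3 * se + 1e-12)

    def test_mean_gradient_closed_form(self):
        # target N(0,1), q = N(m,1): E[dELBO/dm] = -m
        model = standard_normal_model(1)
        q = MeanFieldGaussian(np.array([2.0]), np.zeros(1))
        rng = np.random.default_rng(5)
        grads = np.array([elbo_value_and_grad(q, model, 1, rng)[1][0]
                          for _ in range(20_000)])
        se = grads.std(ddof=1) / np.sqrt(len(grads))
        assert abs(grads.mean() + 2.0) < 3 * se

    def test_common_random_number_finite_differences(self, conjugate):
        model = conjugate.model()
        phi0 = np.array([0.4, -0.2])
        eps = 1e-6

        def value(phi, seed=77):
            q = MeanFieldGaussian(phi[:1], phi[1:])
            return elbo_estimate(q, model, 1, np.random.default_rng(seed))

        q = MeanFieldGaussian(phi0[:1].copy(), phi0[1:].copy())
        _, g = elbo_value_and_grad(q, model, 1, np.random.default_rng(77))
        for j in range(2):
            e = np.zeros(2)
            e[j] = eps
            fd = (value(phi0 + e) - value(phi0 - e)) / (2 * eps)
            assert abs(fd - g[j]) / (abs(fd) + 1e-8) < 1e-4


class FakePointQ:
    """Deterministic sample set with uniform proposal density (testing)."""

    def __init__(self, z):
        self.z = np.atleast_2d(np.asarray(z, dtype=float))
        self.dim = self.z.shape[1]

    def sample(self, rng, n):
        assert n == len(self.z)
        return self.z

    def log_density(self, z):
        return np.zeros(len(np.atleast_2d(z)))


class FakeLogP:
    def __init__(self, values):
        self.values = list(values)
        self.i = 0

    def log_joint(self, z):
        v = self.values[self.i]
        self.i += 1
        return v


class TestSNIS:
    def test_proportional_densities_give_uniform_weights(self):
        model = standard_normal_model(2)
        q = MeanFieldGaussian(np.zeros(2), np.zeros(2))
        batch = snis_batch(q, model, 50, np.random.default_rng(6))
        assert np.allclose(batch.weights, 1 / 50, atol=1e-12)
        assert batch.kl_report == pytest.approx(0.0, abs=1e-12)
        assert batch.ess == pytest.approx(50.0, rel=1e-9)

    def test_two_sample_weight_arithmetic(self):
        q = FakePointQ(np.zeros((2, 1)))
        model = FakeLogP([0.0, np.log(3.0)])
        batch = snis_batch(q, model, 2, np.random.default_rng(0))
        assert np.allclose(batch.weights, [0.25, 0.75], atol=1e-12)

    def test_weights_sum_to_one_and_ess_bounds(self):
        model = gaussian_model([0.5], [0.8])
        q = MeanFieldGaussian(np.zeros(1), np.full(1, np.log(1.2)))
        batch = snis_batch(q, model, 200, np.random.default_rng(7))
        assert batch.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert 1.0 <= batch.ess <= 200.0

    def test_kl_report_matches_analytic_forward_kl(self):
        # p = N(0.5, 0.8^2), q = N(0, 1.2^2): bounded importance ratios
        mp, sp, sq = 0.5, 0.8, 1.2
        analytic = np.log(sq / sp) + (sp ** 2 + mp ** 2) / (2 * sq ** 2) - 0.5
        model = gaussian_model([mp], [sp])
        q = MeanFieldGaussian(np.zeros(1), np.full(1, np.log(sq)))
        rng = np.random.default_rng(8)
        reps = [snis_batch(q, model, 100_000, rng).kl_report for _ in range(8)]
        se = np.std(reps, ddof=1) / np.sqrt(len(reps))
        assert abs(np.mean(reps) - analytic) < 3 * se

    def test_ess_fraction_approaches_one_as_q_approaches_p(self, conjugate):
        model = conjugate.model()
        rng = np.random.default_rng(9)
        fractions = []
        for scale in (3.0, 1.5, 1.0):
            q = MeanFieldGaussian(
                np.array([conjugate.posterior_mean]),
                np.array([np.log(scale * conjugate.posterior_sd)]))
            fractions.append(snis_batch(q, model, 5_000, rng).ess / 5_000)
        assert fractions[0] < fractions[1] < fractions[2]
        assert fractions[2] > 0.99

    def test_degenerate_batch_raises(self):
        q = FakePointQ(np.zeros((2, 1)))
        model = FakeLogP([np.nan, np.nan])

        class NanModel:
            def log_joint(self, z):
                return np.nan

        with pytest.raises(DegenerateBatchError):
            snis_batch(FakePointQ(np.zeros((3, 1))), NanModel(), 3,
                       np.random.default_rng(0))


class TestForwardKLGradient:
    def test_symmetric_samples_zero_mean_gradient(self):
        from glidetree.inference import SNISBatch
        q = MeanFieldGaussian(np.zeros(1), np.zeros(1))
        batch = SNISBatch(np.array([[1.3], [-1.3]]), np.zeros(2),
                          np.array([0.5, 0.5]), 2.0, 0.0)
        g = forward_kl_gradient(batch, q)
        assert abs(g[0]) < 1e-14  # mu component

    def test_single_dominant_weight_limit(self):
        from glidetree.inference import SNISBatch
        mu, sigma = 0.3, 1.5
        q = MeanFieldGaussian(np.array([mu]), np.array([np.log(sigma)]))
        z0 = 2.0
        batch = SNISBatch(np.array([[z0], [5.0]]), np.zeros(2),
                          np.array([1.0, 0.0]), 1.0, 0.0)
        g = forward_kl_gradient(batch, q)
        assert g[0] == pytest.approx(-(z0 - mu) / sigma ** 2, abs=1e-12)

    def test_matches_finite_differences_at_fixed_batch(self):
        from glidetree.inference import SNISBatch
        rng = np.random.default_rng(10)
        z = rng.normal(size=(6, 3))
        w = rng.dirichlet(np.ones(6))
        batch = SNISBatch(z, np.zeros(6), w, 1.0, 0.0)
        phi0 = np.concatenate([rng.normal(size=3), rng.normal(size=3) * 0.3])

        def loss(phi):
            q = MeanFieldGaussian(phi[:3], phi[3:])
            return -np.sum(w * q.log_density(z))

        q = MeanFieldGaussian(phi0[:3].copy(), phi0[3:].copy())
        g = forward_kl_gradient(batch, q)
        for j in range(6):
            e = np.zeros(6)
            e[j] = 1e-7
            fd = (loss(phi0 + e) - loss(phi0 - e)) / 2e-7
            assert abs(fd - g[j]) / (abs(fd) + 1e-10) < 1e-6


class TestFitVI:
    def test_elbo_recovers_conjugate_posterior(self, conjugate):
        model = conjugate.model()
        q, _ = fit_vi(model, objective="elbo", iterations=20_000, seed=1,
                      average_fraction=0.5)
        assert abs(q.mu[0] - conjugate.posterior_mean) < 0.01
        assert abs(np.exp(q.log_sigma[0]) / conjugate.posterior_sd - 1) < 0.05

    def test_forward_kl_recovers_conjugate_posterior(self, conjugate):
        model = conjugate.model()
        q, _ = fit_vi(model, objective="forward_kl", iterations=8_000, seed=2,
                      average_fraction=0.5)
        assert abs(q.mu[0] - conjugate.posterior_mean) < 0.02
        assert abs(np.exp(q.log_sigma[0]) / conjugate.posterior_sd - 1) < 0.10

    def test_full_rank_initialized_from_mean_field(self, conjugate):
        model = conjugate.model()
        mf, _ = fit_vi(model, objective="elbo", iterations=4_000, seed=3)
        fr, _ = fit_vi(model, family="full_rank", init_family=mf,
                       iterations=200, learning_rate=1e-5, seed=3)
        assert isinstance(fr, FullRankGaussian)
        # tiny learning rate: stays near the mean-field optimum
        assert abs(fr.mu[0] - mf.mu[0]) < 0.05
        L = fr.cholesky()
        assert abs(L[0, 0] - np.exp(mf.log_sigma[0])) < 0.05

    def test_same_seed_identical_traces(self, conjugate):
        model = conjugate.model()
        runs = [fit_vi(model, objective="elbo", iterations=500, seed=42,
                       checkpoint_every=100) for _ in range(2)]
        (q1, t1), (q2, t2) = runs
        assert t1.objective == t2.objective
        assert np.array_equal(q1.get_phi(), q2.get_phi())

    def test_forward_kl_never_differentiates_the_model(self, conjugate):
        model = conjugate.model()
        assert model.gradient_evals == 0
        fit_vi(model, objective="forward_kl", iterations=300, seed=4)
        assert model.gradient_evals == 0
        fit_vi(model, objective="elbo", iterations=10, seed=4)
        assert model.gradient_evals > 0

    def test_mode_seeking_vs_mass_covering_on_mixture(self):
        """Reverse KL locks onto one component; forward KL spreads over
        both, so its fitted variance must be larger (5 seeds)."""
        target = mixture_model([-3.0, 3.0], [1.0, 1.0], [0.5, 0.5])
        for seed in range(5):
            qe, _ = fit_vi(target, objective="elbo", iterations=2_000, seed=seed)
            qf, _ = fit_vi(target, objective="forward_kl", iterations=2_000,
                           seed=seed)
            assert np.exp(qf.log_sigma[0]) > np.exp(qe.log_sigma[0])

    def test_unknown_objective_rejected(self, conjugate):
        with pytest.raises(ValueError):
            fit_vi(conjugate.model(), objective="divergence-of-the-week")


class TestHMC:
    def test_standard_normal_moments(self):
        model = standard_normal_model(5)
        res = hmc_sample(model, n_samples=10_000, warmup=1_000, seed=12)
        se = 1.0 / np.sqrt(10_000 / 4)  # conservative ESS discount
        assert np.all(np.abs(res.samples.mean(axis=0)) < 3 * se)
        assert np.all(np.abs(res.samples.var(axis=0) - 1.0) < 0.1)

    def test_leapfrog_energy_error_vanishes_with_step(self):
        model = standard_normal_model(2)
        z = np.array([0.7, -0.3])
        p = np.array([0.2, 0.5])
        mass = np.ones(2)

        def grad_fn(x):
            return model.log_joint_grad(x)

        def hamiltonian(z, p):
            return -model.log_joint(z) + 0.5 * np.sum(p * p)

        z1, p1 = leapfrog(grad_fn, z, p, 1e-4, 10, mass)
        assert abs(hamiltonian(z1, p1) - hamiltonian(z, p)) < 1e-6

    def test_leapfrog_reversibility(self):
        model = standard_normal_model(3)
        rng = np.random.default_rng(13)
        z, p = rng.normal(size=3), rng.normal(size=3)
        mass = np.ones(3)

        def grad_fn(x):
            return model.log_joint_grad(x)

        z1, p1 = leapfrog(grad_fn, z, p, 0.3, 25, mass)
        z2, p2 = leapfrog(grad_fn, z1, -p1, 0.3, 25, mass)
        assert np.max(np.abs(z2 - z)) < 1e-8
        assert np.max(np.abs(-p2 - p)) < 1e-8


class TestMAP:
    def test_conjugate_mode(self, conjugate):
        res = map_optimize(conjugate.model())
        assert abs(res.values["theta"][0] - conjugate.posterior_mean) < 1e-6
        assert res.grad_norm < 1e-4

    def test_pure_prior_mode_at_zero(self):
        res = map_optimize(standard_normal_model(3))
        assert np.max(np.abs(res.x)) < 1e-6

    def test_jc69_two_taxon_distance(self):
        """MAP branch length under a flat prior equals the analytic JC69
        distance d = -3/4 log(1 - 4/3 p) from the mismatch fraction."""
        seqs = ["ACGTACGTACGTACGTACGA", "ACGTACCTACGAACGTACGA"]
        aln = Alignment.from_sequences(["a", "b"], seqs)
        tree = TimeTree(["a", "b"], [[0, 1]], np.array([0.0, 0.0, 0.1]))

        def lik(values):
            heights = ad.concatenate([np.zeros(2), values["h"]])
            return pruning_log_likelihood(tree, aln, None, None,
                                          np.ones(1), np.ones(1), 1.0,
                                          heights=heights)

        model = JointPosterior([ParameterBlock("h", Identity(1))],
                               [("likelihood", lik)])
        res = map_optimize(model, x0=np.array([0.05]))
        p_hat = sum(a != b for a, b in zip(*seqs)) / len(seqs[0])
        d_hat = -0.75 * np.log(1 - 4 * p_hat / 3)
        assert abs(2 * res.x[0] - d_hat) < 1e-4


def test_adam_decay_shrinks_steps():
    opt = Adam(1, lr=0.1, decay=True, decay_t0=10.0)
    phi = np.zeros(1)
    steps = []
    for _ in range(200):
        new = opt.step(phi, np.ones(1))
        steps.append(abs(new[0] - phi[0]))
        phi = new
    assert steps[-1] < steps[5]
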