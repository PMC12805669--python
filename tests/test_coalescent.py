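"""Coalescent densities for constant, skygrid, and skyglide demographies."""

import numpy as np
import pytest
from scipy.integrate import quad

from glidetree.coalescent import (CoalescentError, DemographicGrid,
                                  coalescent_log_density,
                                  coalescent_log_density_heights,
                                  constant_coalescent_log_density,
                                  gmrf_log_prior, inverse_pop_integral,
                                  pop_size_at)
from glidetree.tree import TimeTree, coalescent_intervals
from tests.conftest import random_tree


def grid_of(cutoff, gammas):
    gammas = np.asarray(gammas, dtype=float)
    return DemographicGrid(cutoff, len(gammas) - 1, gammas)


class TestPopSize:
    def test_flat_trajectory_both_kinds(self):
        g = grid_of(10.0, np.log([3.0] * 5))
        for kind in ("linear", "constant"):
            for t in (0.0, 2.5, 7.3, 10.0, 25.0):
                assert float(pop_size_at(g, t, kind)) == pytest.approx(3.0)

    def test_linear_midpoint_interpolation(self):
        g = grid_of(1.0, np.log([1.0, 2.0]))
        assert float(pop_size_at(g, 0.5, "linear")) == pytest.approx(1.5)

    def test_beyond_cutoff_uses_last_value(self):
        g = grid_of(1.0, np.log([1.0, 2.0]))
        for kind in ("linear", "constant"):
            assert float(pop_size_at(g, 5.0, kind)) == pytest.approx(2.0)

    def test_negative_time_rejected(self):
        g = grid_of(1.0, np.log([1.0, 2.0]))
        with pytest.raises(CoalescentError):
            pop_size_at(g, -0.1, "linear")

    def test_continuity_and_jumps_at_grid_points(self, rng):
        g = grid_of(5.0, rng.normal(size=6))
        theta = np.exp(g.log_pop_sizes)
        eps = 1e-9
        for i in range(1, 5):
            x = g.times[i]
            below = float(pop_size_at(g, x - eps, "linear"))
            above = float(pop_size_at(g, x + eps, "linear"))
            assert abs(above - below) < 1e-6  # continuous (up to eps slope)
            j_below = float(pop_size_at(g, x - eps, "constant"))
            j_above = float(pop_size_at(g, x + eps, "constant"))
            assert abs(j_below - theta[i - 1]) < 1e-6
            assert abs(j_above - theta[i]) < 1e-12


class TestInverseIntegral:
    def test_empty_interval(self):
        g = grid_of(1.0, np.log([1.0, 2.0]))
        assert float(inverse_pop_integral(g, 0.4, 0.4, "linear")) == 0.0

    def test_unit_cell_closed_forms(self):
        g = grid_of(1.0, np.log([1.0, 2.0]))
        assert float(inverse_pop_integral(g, 0.0, 1.0, "linear")) \
            == pytest.approx(np.log(2.0), abs=1e-12)
        assert float(inverse_pop_integral(g, 0.0, 1.0, "constant")) \
            == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("kind", ["linear", "constant"])
    def test_matches_adaptive_quadrature(self, kind, rng):
        for _ in range(15):
            g = grid_of(float(rng.uniform(2, 10)), rng.normal(size=6))
            u = float(rng.uniform(0, g.cutoff))
            v = float(u + rng.uniform(0, 1.5 * g.cutoff))
            val = float(inverse_pop_integral(g, u, v, kind))
            pts = [x for x in g.times if u < x < v]
            oracle = quad(lambda t: 1.0 / float(pop_size_at(g, t, kind)),
                          u, v, points=pts or None, limit=400,
                          epsabs=1e-12, epsrel=1e-12)[0]
            assert abs(val - oracle) < 1e-9

    def test_additivity(self, rng):
        g = grid_of(4.0, rng.normal(size=5))
        u, v, w = 0.3, 2.1, 5.6
        for kind in ("linear", "constant"):
            whole = float(inverse_pop_integral(g, u, w, kind))
            split = (float(inverse_pop_integral(g, u, v, kind))
                     + float(inverse_pop_integral(g, v, w, kind)))
            assert abs(whole - split) < 1e-10

    def test_reversed_interval_rejected(self):
        g = grid_of(1.0, np.log([1.0, 2.0]))
        with pytest.raises(CoalescentError):
            inverse_pop_integral(g, 1.0, 0.5, "linear")


class TestDensity:
    def test_two_tips_constant_closed_form(self):
        t = TimeTree(["a", "b"], [[0, 1]], np.array([0.0, 0.0, 1.0]))
        iv = coalescent_intervals(t)
        assert float(constant_coalescent_log_density(iv, 1.0)) \
            == pytest.approx(-1.0, abs=1e-12)

    def test_heterochronous_hand_computation(self):
        # tips 0,0,1; coalescences 0.5 and 2; N = 1
        t = TimeTree(["a", "b", "c"], [[0, 1], [3, 2]],
                     np.array([0.0, 0.0, 1.0, 0.5, 2.0]))
        iv = coalescent_intervals(t)
        assert float(constant_coalescent_log_density(iv, 1.0)) \
            == pytest.approx(-1.5, abs=1e-12)

    def test_model_nesting_flat_trajectory(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 15))
            t = random_tree(rng, n, pop_size=2.0,
                            heterochronous=bool(rng.integers(2)))
            iv = coalescent_intervals(t)
            level = float(rng.uniform(0.5, 3.0))
            g = grid_of(float(rng.uniform(1, 6)), np.log([level] * 6))
            ref = float(constant_coalescent_log_density(iv, level))
            for kind in ("linear", "constant"):
                assert abs(float(coalescent_log_density(iv, g, kind)) - ref) < 1e-10

    def test_vectorized_heights_path_matches_interval_path(self, rng):
        for _ in range(10):
            t = random_tree(rng, 8, heterochronous=True)
            g = grid_of(2.0, rng.normal(size=7))
            iv = coalescent_intervals(t)
            n = t.n_taxa
            for kind in ("linear", "constant"):
                a = float(coalescent_log_density(iv, g, kind))
                b = float(coalescent_log_density_heights(
                    t.heights[:n], t.heights[n:], g, kind))
                assert abs(a - b) < 1e-10

    def test_skyglide_gradient_continuous_across_grid_crossing(self):
        """Nudging a coalescent time across a grid point leaves the skyglide
        gamma-gradient continuous, while the skygrid *density* jumps."""
        tips = np.zeros(2)
        g = DemographicGrid(2.0, 2, np.log([1.0, 4.0, 2.0]))  # points 0,1,2
        eps = 1e-6

        def gamma_grad(coal_t, kind):
            base = np.array(g.log_pop_sizes)
            out = np.empty(3)
            for j in range(3):
                gp, gm = base.copy(), base.copy()
                gp[j] += eps
                gm[j] -= eps
                dp = float(coalescent_log_density_heights(
                    tips, [coal_t], DemographicGrid(2.0, 2, gp), kind))
                dm = float(coalescent_log_density_heights(
                    tips, [coal_t], DemographicGrid(2.0, 2, gm), kind))
                out[j] = (dp - dm) / (2 * eps)
            return out

        below = gamma_grad(1.0 - 1e-6, "linear")
        above = gamma_grad(1.0 + 1e-6, "linear")
        assert np.max(np.abs(above - below)) < 1e-3

        d_below = float(coalescent_log_density_heights(tips, [1.0 - 1e-6],
                                                       g, "constant"))
        d_above = float(coalescent_log_density_heights(tips, [1.0 + 1e-6],
                                                       g, "constant"))
        expected_jump = abs(np.log(4.0) - np.log(1.0))
        assert abs(d_above - d_below) == pytest.approx(expected_jump, abs=1e-4)


class TestGMRF:
    def test_flat_field_value(self):
        gam = np.full(4, 1.7)
        kappa = 2.5
        assert float(gmrf_log_prior(gam, kappa)) \
            == pytest.approx(1.5 * np.log(kappa / (2 * np.pi)), abs=1e-12)

    def test_shift_invariance(self, rng):
        gam = rng.normal(size=6)
        v1 = float(gmrf_log_prior(gam, 1.3))
        v2 = float(gmrf_log_prior(gam + 42.0, 1.3))
        assert v1 == pytest.approx(v2, abs=1e-10)

    def test_arithmetic_example(self):
        val = float(gmrf_log_prior(np.array([0.0, 1.0, 0.0]), 2.0))
        assert val == pytest.approx(np.log(2 / (2 * np.pi)) - 2.0, abs=1e-9)
        assert val == pytest.approx(-3.144729, abs=1e-6)

    def test_invalid_precision(self):
        with pytest.raises(CoalescentError):
            gmrf_log_prior(np.zeros(3), -1.0)
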