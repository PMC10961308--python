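"""Energy terms and the weighted objective."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pics.losses import (
    LossWeights,
    chan_vese_energy,
    internal_energy,
    shape_prior_energy,
    total_loss,
)
from pics.raster import ImageGrid, rasterize_polygon, region_means
from pics.spline import derivatives_at_knots, fit_periodic_cubic, KnotDerivatives

from conftest import random_contour
from helpers_oracles import chan_vese_loop, total_loss_composed


def circle_knots(n, radius, center=(0.0, 0.0)):
    ang = 2 * np.pi * np.arange(n) / n
    return np.stack(
        [center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)], axis=1
    )


class TestInternalEnergy:
    def test_zero_derivatives_give_zero(self):
        z = np.zeros(6)
        assert internal_energy(KnotDerivatives(z, z, z, z)) == (0.0, 0.0)

    def test_quadratic_scaling_in_coordinates(self, rng):
        knots = random_contour(rng)
        j1, j1ss = internal_energy(derivatives_at_knots(fit_periodic_cubic(knots)))
        j2, j2ss = internal_energy(
            derivatives_at_knots(fit_periodic_cubic(2.0 * knots))
        )
        assert j2 == pytest.approx(4.0 * j1, rel=1e-10)
        assert j2ss == pytest.approx(4.0 * j1ss, rel=1e-10)

    def test_matches_dense_finite_difference_summation(self):
        """Knot-averaged energies agree with an independent summation over
        finite-difference derivative estimates of the dense curve."""
        from pics.spline import evaluate_segment

        knots = circle_knots(16, 5.0)
        model = fit_periodic_cubic(knots)
        eps = 1e-5
        du, dv, d2u, d2v = [], [], [], []
        for i in range(16):
            # centered stencils straddling knot i (s=0 of segment i)
            up, vp = evaluate_segment(model, i, eps)
            u0, v0 = evaluate_segment(model, i, 0.0)
            um, vm = evaluate_segment(model, (i - 1) % 16, 1.0 - eps)
            du.append((up - um) / (2 * eps))
            dv.append((vp - vm) / (2 * eps))
            d2u.append((up - 2 * u0 + um) / eps**2)
            d2v.append((vp - 2 * v0 + vm) / eps**2)
        j_s_fd = np.mean(np.array(du) ** 2 + np.array(dv) ** 2)
        j_ss_fd = np.mean(np.array(d2u) ** 2 + np.array(d2v) ** 2)
        j_s, j_ss = internal_energy(derivatives_at_knots(model))
        assert j_s == pytest.approx(j_s_fd, rel=1e-3)
        assert j_ss == pytest.approx(j_ss_fd, rel=1e-3)


class TestChanVese:
    def test_perfect_partition_is_zero(self):
        img = np.zeros((16, 16))
        img[4:10, 5:12] = 1.0
        grid = ImageGrid(img, normalize=False)
        mask = (img == 1.0).astype(np.uint8)
        stats = region_means(grid, mask)
        assert chan_vese_energy(grid, mask, stats, gamma=0.0) == pytest.approx(0.0, abs=1e-20)

    def test_constant_image_is_zero_for_any_mask(self, rng):
        grid = ImageGrid(np.full((8, 8), 0.7), normalize=False)
        mask = (rng.uniform(size=(8, 8)) > 0.4).astype(np.uint8)
        mask[0, 0] = 1
        stats = region_means(grid, mask)
        assert chan_vese_energy(grid, mask, stats, 0.0) == pytest.approx(0.0, abs=1e-18)

    def test_matches_per_pixel_loop_with_gradient_term(self, rng):
        for _ in range(5):
            img = rng.uniform(size=(8, 8))
            mask = (rng.uniform(size=(8, 8)) > 0.5).astype(np.uint8)
            mask[3, 3] = 1
            grid = ImageGrid(img, normalize=False)
            stats = region_means(grid, mask)
            ours = chan_vese_energy(grid, mask, stats, gamma=0.5)
            assert ours == pytest.approx(chan_vese_loop(img, mask, 0.5), rel=1e-12)

    def test_shape_mismatch_raises(self):
        grid = ImageGrid(np.zeros((8, 8)), normalize=False)
        from pics.raster import RegionStats

        with pytest.raises(ValueError):
            chan_vese_energy(grid, np.ones((9, 8)), RegionStats(0, 0, 1, 71), 0.0)


class TestShapePrior:
    def test_zero_curvature_gives_zero(self):
        assert shape_prior_energy(np.zeros(12)) == 0.0

    def test_circle_value_is_inverse_radius_squared(self):
        kappa = np.full(32, 0.1)  # analytic curvature of a radius-10 circle
        assert shape_prior_energy(kappa) == pytest.approx(0.01, rel=1e-12)
        from pics.spline import curvature_at_knots

        k_spline = curvature_at_knots(
            derivatives_at_knots(fit_periodic_cubic(circle_knots(32, 10.0)))
        )
        assert shape_prior_energy(k_spline) == pytest.approx(0.01, rel=0.02)

    def test_notched_contour_exceeds_convex_counterpart(self, rng):
        from pics.spline import curvature_at_knots

        def j_shape(knots):
            return shape_prior_energy(
                curvature_at_knots(derivatives_at_knots(fit_periodic_cubic(knots)))
            )

        wins = 0
        trials = 40
        for _ in range(trials):
            n = int(rng.integers(10, 16))
            convex = circle_knots(n, float(rng.uniform(8, 14)))
            notched = convex.copy()
            notched[int(rng.integers(n))] *= rng.uniform(0.3, 0.6)  # pull inward
            wins += j_shape(notched) > j_shape(convex)
        assert wins / trials >= 0.95


class TestTotalLoss:
    def test_perfect_segmentation_with_region_weight_only(self):
        img = np.zeros((32, 32))
        img[8:24, 8:24] = 1.0
        grid = ImageGrid(img, normalize=False)
        square = np.array([[7.5, 7.5], [23.5, 7.5], [23.5, 23.5], [7.5, 23.5]])
        bd = total_loss(square, grid, LossWeights(0.0, 0.0, 1.0, 0.0, 0.0))
        assert bd.total == pytest.approx(0.0, abs=1e-18)

    def test_sigma_linearity_is_exact(self, rng):
        img = rng.uniform(size=(24, 24))
        grid = ImageGrid(img, normalize=False)
        knots = random_contour(rng, center=(12.0, 12.0), r_min=4, r_max=9)
        w0 = LossWeights(0.3, 0.02, 10.0, 0.1, 0.0)
        w1 = LossWeights(0.3, 0.02, 10.0, 0.1, 7.5)
        b0 = total_loss(knots, grid, w0)
        b1 = total_loss(knots, grid, w1)
        assert b1.total - 7.5 * b1.j_shape == pytest.approx(b0.total, rel=1e-14)

    def test_matches_composed_brute_force_oracles(self, rng):
        """Spot check of the full objective against the composed
        brute-force recomputation (dense spline solve + pixel loops)."""
        for _ in range(5):
            img = rng.uniform(size=(16, 16))
            grid = ImageGrid(img, normalize=False)
            knots = random_contour(rng, n_knots=int(rng.integers(5, 9)),
                                   center=(8.0, 8.0), r_min=2.5, r_max=7.0)
            a, b, m, g, s = 0.5, 1e-2, 1e3, 0.25, 2.0
            bd = total_loss(knots, grid, LossWeights(a, b, m, g, s))
            want = total_loss_composed(knots, img, a, b, m, g, s)
            got = bd.total + s * 0.0  # total already includes sigma * j_shape
            assert got == pytest.approx(want, rel=1e-10)

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 2**31 - 1))
    def test_every_term_non_negative_and_weighted_sum_exact(self, seed):
        r = np.random.default_rng(seed)
        img = r.uniform(size=(16, 16))
        grid = ImageGrid(img, normalize=False)
        knots = random_contour(r, center=(8.0, 8.0), r_min=3.0, r_max=7.0)
        w = LossWeights(*r.uniform(0, 2, size=4), sigma=r.uniform(0, 2))
        w = LossWeights(w.alpha, w.beta, w.mu + 1e-6, w.gamma, w.sigma)
        bd = total_loss(knots, grid, w)
        for term in (bd.j_psi_s, bd.j_psi_ss, bd.j_cv, bd.j_shape):
            assert term >= 0.0
        assert bd.total == w.alpha * bd.j_psi_s + w.beta * bd.j_psi_ss + \
            w.mu * bd.j_cv + w.sigma * bd.j_shape
        assert bd.j_int == w.alpha * bd.j_psi_s + w.beta * bd.j_psi_ss
        assert bd.j_ext == w.mu * bd.j_cv

    def test_translation_invariance_of_geometry_terms(self, rng):
        img = rng.uniform(size=(24, 24))
        big = np.tile(img, (2, 2))[:32, :32]
        grid = ImageGrid(big, normalize=False)
        knots = random_contour(rng, center=(10.0, 10.0), r_min=3.0, r_max=7.0)
        w = LossWeights(1.0, 1.0, 1.0, 0.0, 1.0)
        b0 = total_loss(knots, grid, w)
        b1 = total_loss(knots + [5.0, 5.0], grid, w)
        assert b1.j_psi_s == pytest.approx(b0.j_psi_s, rel=1e-12)
        assert b1.j_psi_ss == pytest.approx(b0.j_psi_ss, rel=1e-12)
        assert b1.j_shape == pytest.approx(b0.j_shape, rel=1e-12)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(-1.0, 0.0, 1.0)
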