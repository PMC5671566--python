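"""Constrained quadric fitting and ellipsoid geometry."""

import numpy as np
import pytest

from conftest import random_ellipsoid_points
from somaburst.ellipsoid import (
    EllipsoidGeometry,
    QuadricCoefficients,
    ScaleFrame,
    fit_ellipsoid,
    fit_quadric,
    quadric_to_geometry,
    scale_points,
    unscale_quadric,
    volume_filter,
    voxelize,
)


class TestScalePoints:
    def test_unit_box(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 10, size=(50, 3))
        scaled, frame = scale_points(pts)
        assert scaled.min() >= 0 and scaled.max() <= 1
        assert scaled.min(axis=0) == pytest.approx([0, 0, 0])
        assert scaled.max(axis=0) == pytest.approx([1, 1, 1])
        np.testing.assert_allclose(frame.invert(scaled), pts, atol=1e-12)

    def test_degenerate_axis_scale_one(self):
        pts = np.zeros((12, 3))
        pts[:, 1] = np.linspace(0, 5, 12)
        _scaled, frame = scale_points(pts)
        assert frame.scales[0] == 1.0 and frame.scales[2] == 1.0

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="insufficient"):
            scale_points(np.zeros((9, 3)))


class TestFitQuadric:
    def test_unit_sphere_coefficients(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=(258, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        coeffs = fit_quadric(u)
        a = coeffs.a / np.abs(coeffs.a[0])
        np.testing.assert_allclose(a[:3], np.sign(a[0]) * np.ones(3), atol=1e-8)
        np.testing.assert_allclose(a[3:9], 0, atol=1e-8)
        assert a[9] == pytest.approx(-a[0], abs=1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_recovery_random_ellipsoids(self, seed):
        rng = np.random.default_rng(seed)
        pts, center, axes, _rot = random_ellipsoid_points(rng)
        _coeffs, geom = fit_ellipsoid(pts)
        np.testing.assert_allclose(geom.center, center, rtol=0, atol=1e-6 * max(abs(center)))
        np.testing.assert_allclose(geom.semi_axes, axes, rtol=1e-6)

    def test_constraint_normalization(self):
        """Scaled-frame coefficients satisfy 4J - I^2 = 1 whenever the shape
        is representable under the constraint (axis ratio < 2)."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            axes = np.sort(rng.uniform(5, 8, 3))[::-1]  # ratio < 2: representable
            u = rng.normal(size=(258, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            pts = rng.uniform(0, 50, 3) + axes * u
            scaled, _frame = scale_points(pts)
            coeffs = fit_quadric(scaled)
            assert coeffs.constraint_value() == pytest.approx(1.0, abs=1e-9)

    def test_noise_robustness_five_percent(self):
        axes = np.array([5.0, 4.0, 3.0])
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            u = rng.normal(size=(258, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            pts = 50 + axes * u + rng.normal(0, 0.2, (258, 3))
            _c, geom = fit_ellipsoid(pts)
            assert np.abs(geom.semi_axes - axes).max() / axes.max() < 0.05

    def test_permutation_and_frame_invariance(self):
        rng = np.random.default_rng(5)
        pts, _c, _a, _r = random_ellipsoid_points(rng)
        _c1, g1 = fit_ellipsoid(pts)
        _c2, g2 = fit_ellipsoid(pts[rng.permutation(len(pts))])
        np.testing.assert_allclose(g1.center, g2.center, atol=1e-8)
        np.testing.assert_allclose(g1.semi_axes, g2.semi_axes, atol=1e-8)

    def test_coplanar_cloud_rejected(self):
        pts = np.zeros((30, 3))
        pts[:, 1:] = np.random.default_rng(6).normal(size=(30, 2))
        with pytest.raises(ValueError):
            fit_quadric(pts)


class TestUnscale:
    def test_identity_frame_unchanged(self):
        rng = np.random.default_rng(7)
        u = rng.normal(size=(100, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        coeffs = fit_quadric(3.0 * u)
        frame = ScaleFrame(np.zeros(3), np.ones(3))
        out = unscale_quadric(coeffs, frame)
        ratio = out.a / coeffs.a
        np.testing.assert_allclose(ratio, ratio[0], atol=1e-9)

    def test_translation_keeps_quadratic_terms(self):
        rng = np.random.default_rng(8)
        pts, _c, _a, _r = random_ellipsoid_points(rng, center_range=0.0)
        coeffs = fit_quadric(pts)
        frame = ScaleFrame(np.array([3.0, -2.0, 5.0]), np.ones(3))
        out = unscale_quadric(coeffs, frame)
        s = out.a[0] / coeffs.a[0]
        np.testing.assert_allclose(out.a[:6], s * coeffs.a[:6], atol=1e-9)

    def test_random_frame_roundtrip_residual(self):
        """Original-frame surface points satisfy the unscaled quadric."""
        rng = np.random.default_rng(9)
        pts, _c, _a, _r = random_ellipsoid_points(rng, n=100)
        scaled, frame = scale_points(pts)
        coeffs = unscale_quadric(fit_quadric(scaled), frame)
        vals = coeffs.evaluate(pts)
        assert np.abs(vals).max() < 1e-6


class TestGeometry:
    def test_sphere_closed_forms(self):
        a = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, -25.0])
        geom = quadric_to_geometry(QuadricCoefficients(a))
        np.testing.assert_allclose(geom.semi_axes, [5, 5, 5], atol=1e-12)
        assert geom.volume == pytest.approx(500 * np.pi / 3, rel=1e-9)
        assert geom.area == pytest.approx(4 * np.pi * 25, rel=1e-4)

    def test_axis_aligned_543_volume(self):
        a = np.array([1 / 25, 1 / 16, 1 / 9, 0, 0, 0, 0, 0, 0, -1.0])
        geom = quadric_to_geometry(QuadricCoefficients(a))
        assert geom.volume == pytest.approx(80 * np.pi, rel=1e-9)

    def test_rotation_invariant_semi_axes(self):
        rng = np.random.default_rng(10)
        from somaburst.phantom import _rotation_matrix

        axes = np.array([6.0, 4.0, 3.0])
        u = rng.normal(size=(258, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        rot = _rotation_matrix((0.7, 0.2, 1.1))
        _c0, g0 = fit_ellipsoid(axes * u)
        _c1, g1 = fit_ellipsoid((rot @ (axes * u).T).T)
        np.testing.assert_allclose(g0.semi_axes, g1.semi_axes, atol=1e-9)
        np.testing.assert_allclose(g0.rotation @ g0.rotation.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(g1.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_non_ellipsoid_rejected(self):
        hyperboloid = np.array([1, 1, -1, 0, 0, 0, 0, 0, 0, -1.0])
        with pytest.raises(ValueError):
            quadric_to_geometry(QuadricCoefficients(hyperboloid))


class TestVoxelize:
    def _sphere_coeffs(self, center, r):
        cz, cy, cx = center
        a = np.array([1.0, 1, 1, 0, 0, 0, -2 * cz, -2 * cy, -2 * cx,
                      cz**2 + cy**2 + cx**2 - r**2])
        return QuadricCoefficients(a)

    def test_sphere_volume_within_three_percent(self):
        coeffs = self._sphere_coeffs((12, 12, 12), 4.5)
        vox = voxelize(coeffs, (24, 24, 24))
        continuous = 4 / 3 * np.pi * 4.5**3
        assert abs(len(vox) - continuous) / continuous < 0.03

    def test_out_of_bounds_empty(self):
        coeffs = self._sphere_coeffs((100, 100, 100), 4.0)
        assert len(voxelize(coeffs, (20, 20, 20))) == 0

    def test_integer_translation_exact(self):
        v0 = voxelize(self._sphere_coeffs((10, 10, 10), 4.2), (40, 40, 40))
        v1 = voxelize(self._sphere_coeffs((13, 15, 11), 4.2), (40, 40, 40))
        np.testing.assert_array_equal(v1, v0 + np.array([3, 5, 1]))


class TestVolumeFilter:
    def test_below_threshold_removed(self):
        segs = [np.zeros((4000, 3)), np.zeros((5000, 3))]
        kept = volume_filter(segs, 4200)
        assert len(kept) == 1 and len(kept[0]) == 5000

    def test_zero_threshold_identity(self):
        segs = [np.zeros((10, 3)), np.zeros((1, 3))]
        assert len(volume_filter(segs, 0)) == 2

    def test_all_removed_ok(self):
        assert volume_filter([np.zeros((10, 3))], 100) == []
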