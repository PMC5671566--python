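"""Ray core geometry and distance-map Rayburst sampling."""

import numpy as np
import pytest

from conftest import digital_ball
from somaburst.localize import distance_transform
from somaburst.rayburst import build_ray_core, cast_ray, sample_surface


class TestRayCore:
    def test_icosahedron_exact(self):
        core = build_ray_core(12)
        assert core.count == 12
        dots = np.clip(core.directions @ core.directions.T, -1, 1)
        np.fill_diagonal(dots, -1)
        min_angles = np.degrees(np.arccos(dots.max(axis=1)))
        np.testing.assert_allclose(min_angles, 63.43494882, atol=1e-6)

    @pytest.mark.parametrize("n", [66, 258])
    def test_requested_count_unit_norm_and_balance(self, n):
        core = build_ray_core(n)
        assert core.count == n
        np.testing.assert_allclose(np.linalg.norm(core.directions, axis=1), 1.0, atol=1e-9)
        assert np.linalg.norm(core.directions.sum(axis=0)) <= 0.1 * np.sqrt(n)

    @pytest.mark.parametrize("n", [66, 258])
    def test_antipodal_symmetry(self, n):
        d = build_ray_core(n).directions
        for v in d:
            assert np.min(np.linalg.norm(d + v, axis=1)) < 1e-9

    @pytest.mark.parametrize("n", [66, 162, 258])
    def test_near_uniform_gap_ratio(self, n):
        d = build_ray_core(n).directions
        dots = np.clip(d @ d.T, -1, 1)
        np.fill_diagonal(dots, -1)
        nn = np.arccos(dots.max(axis=1))
        assert nn.max() / nn.min() <= 2.0

    def test_too_few_rays_rejected(self):
        with pytest.raises(ValueError):
            build_ray_core(5)


class TestCastRay:
    def test_ball_rays_stop_at_surface(self):
        r = 8
        c = 1.5 * r
        mask = digital_ball((3 * r, 3 * r, 3 * r), (c, c, c), r)
        dmap = distance_transform(mask)
        for direction in np.eye(3):
            ray = cast_ray(dmap, (c, c, c), direction, max_range=3 * r)
            assert ray.stop_reason == "background"
            assert abs(ray.outer_radius - r) <= 1.0

    def test_touching_pair_neck_stop(self):
        """The ray toward a touching neighbour stops at the neck minimum."""
        shape = (40, 64, 40)
        mask = digital_ball(shape, (20, 26, 20), 8) | digital_ball(shape, (20, 38, 20), 8)
        dmap = distance_transform(mask)
        ray = cast_ray(dmap, (20, 26, 20), (0, 1, 0), max_range=30)
        assert ray.stop_reason == "distance_increase"
        line = dmap.dist[20, 26:39, 20]
        oracle_neck = float(np.argmin(line))
        assert abs(ray.outer_radius - oracle_neck) <= 1.0

    def test_flat_profile_records_inner_before_outer(self):
        """Decrease -> plateau -> background: inner at the plateau onset."""
        d = np.zeros((5, 5, 24))
        d[2, 2, 1:20] = np.concatenate([[6, 5, 4, 3], np.full(12, 3.0), [2, 1, 0.4]])
        ray = cast_ray(d, (2, 2, 1), (0, 0, 1), step=1.0, max_range=22)
        assert ray.stop_reason == "background"
        assert ray.inner_radius == pytest.approx(3.0)
        assert ray.inner_radius < ray.outer_radius

    def test_seed_on_background_rejected(self):
        d = np.zeros((5, 5, 5))
        with pytest.raises(ValueError, match="foreground"):
            cast_ray(d, (2, 2, 2), (0, 0, 1))


class TestSampleSurface:
    @pytest.mark.parametrize("r", [5, 8, 12])
    def test_ball_radius_recovery(self, r):
        c = float(int(1.5 * r))
        mask = digital_ball((3 * r, 3 * r, 3 * r), (c, c, c), r)
        dmap = distance_transform(mask)
        sample = sample_surface(dmap, (c, c, c), build_ray_core(258), max_range=3.0 * r)
        outer = np.array([ray.outer_radius for ray in sample.rays])
        assert abs(outer.mean() - r) <= 1.0
        assert np.abs(outer - r).max() <= 2.0
        assert all(ray.stop_reason == "background" for ray in sample.rays)

    def test_isolated_ball_not_clipped(self):
        r, c = 8, 12.0
        mask = digital_ball((24, 24, 24), (c, c, c), r)
        sample = sample_surface(distance_transform(mask), (c, c, c), build_ray_core(66))
        assert not any(ray.stop_reason == "clipped_by_inner" for ray in sample.rays)
        inner = np.array([ray.inner_radius for ray in sample.rays])
        np.testing.assert_allclose(inner, r, atol=1.5)

    def test_runaway_ray_clipped_to_alpha_median(self):
        """In an elongated slab, near-axial rays run far along the constant
        distance ridge; the alpha-median inner-boundary fix bounds them."""
        mask = np.zeros((14, 14, 64), dtype=bool)
        mask[1:13, 1:13, 1:60] = True
        dmap = distance_transform(mask)
        sample = sample_surface(
            dmap, (7.0, 7.0, 8.0), build_ray_core(66), max_range=60, alpha_clip=2.0
        )
        inner = np.array([r.inner_radius for r in sample.rays])
        bound = 2.0 * np.median(inner)
        outer = np.array([r.outer_radius for r in sample.rays])
        assert any(r.stop_reason == "clipped_by_inner" for r in sample.rays)
        assert outer.max() <= bound + 1e-9
        assert bound < 30  # far below the slab's long extent

    def test_point_cloud_count_follows_core(self, ):
        shape = (40, 64, 40)
        mask = digital_ball(shape, (20, 26, 20), 8) | digital_ball(shape, (20, 38, 20), 8)
        dmap = distance_transform(mask)
        for n in (66, 258):
            sample = sample_surface(dmap, (20.0, 26.0, 20.0), build_ray_core(n))
            assert len(sample.points) == n

    def test_rotation_robustness(self):
        """Rotating mask and ray directions together by 90 deg leaves the
        per-ray sampled radii unchanged (up to interpolation)."""
        shape = (36, 36, 36)
        zz, yy, xx = np.indices(shape)
        mask = ((zz - 18) / 8.0) ** 2 + ((yy - 18) / 6.0) ** 2 + ((xx - 18) / 5.0) ** 2 <= 1
        rotated = np.rot90(mask, k=1, axes=(1, 2))  # (z, y, x) -> (z, N-1-x, y)
        core = build_ray_core(66)
        rot_dirs = np.column_stack(
            [core.directions[:, 0], -core.directions[:, 2], core.directions[:, 1]]
        )
        s0 = sample_surface(distance_transform(mask), (18.0, 18.0, 18.0), core)
        s1 = sample_surface(
            distance_transform(rotated), (18.0, 17.0, 18.0), type(core)(rot_dirs)
        )
        r0 = np.array([r.outer_radius for r in s0.rays])
        r1 = np.array([r.outer_radius for r in s1.rays])
        assert np.abs(r0 - r1).max() <= 1.0

    def test_touching_pair_surfaces_separate(self):
        """The two seeds' outer points stay on their own sides of the neck."""
        shape = (40, 64, 40)
        mask = digital_ball(shape, (20, 26, 20), 8) | digital_ball(shape, (20, 38, 20), 8)
        dmap = distance_transform(mask)
        core = build_ray_core(258)
        pa = sample_surface(dmap, (20.0, 26.0, 20.0), core).points
        pb = sample_surface(dmap, (20.0, 38.0, 20.0), core).points
        neck_y = 32.0
        overflow_a = np.mean(pa[:, 1] > neck_y + 1)
        overflow_b = np.mean(pb[:, 1] < neck_y - 1)
        assert overflow_a < 0.1
        assert overflow_b < 0.1
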