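import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from betapocket.sphere_geometry import (
    DegenerateInputError,
    Sphere,
    equal_volume_radius,
    minimum_enclosing_sphere,
    pca_box_extents,
    tangent_probe_centers,
    union_volume,
)

FOUR_THIRDS_PI = 4.0 * math.pi / 3.0


def random_spheres(n, seed, box=5.0, rmax=2.0):
    rng = np.random.default_rng(seed)
    return [
        Sphere(rng.uniform(-box, box, 3), rng.uniform(0.2, rmax))
        for _ in range(n)
    ]


# ---------------------------------------------------------------------- mes


class TestMinimumEnclosingSphere:
    def test_single_ball_is_identity(self):
        s = minimum_enclosing_sphere([Sphere([1.0, 2.0, 3.0], 1.5)])
        assert np.allclose(s.center, [1, 2, 3]) and s.radius == 1.5

    def test_two_collinear_balls_forced_by_tangency(self):
        s = minimum_enclosing_sphere([Sphere([0, 0, 0], 1.0), Sphere([4, 0, 0], 2.0)])
        assert np.allclose(s.center, [2.5, 0, 0], atol=1e-5)
        assert s.radius == pytest.approx(3.5, abs=1e-6)

    def test_contained_ball_ignored(self):
        s = minimum_enclosing_sphere([Sphere([0, 0, 0], 3.0), Sphere([1, 0, 0], 0.5)])
        assert s.radius == pytest.approx(3.0, abs=1e-6)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            minimum_enclosing_sphere([])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_grid_search_oracle(self, seed):
        """Radius agrees with an independent multi-resolution grid search."""
        spheres = random_spheres(20, seed)
        got = minimum_enclosing_sphere(spheres)

        centers = np.array([s.center for s in spheres])
        radii = np.array([s.radius for s in spheres])

        def worst(c):
            return (np.linalg.norm(centers - c, axis=1) + radii).max()

        # coarse-to-fine grid descent, independent of the SLSQP path
        best = centers.mean(axis=0)
        half = 8.0
        for _ in range(12):
            axes = [np.linspace(best[k] - half, best[k] + half, 9) for k in range(3)]
            grid = np.stack(np.meshgrid(*axes, indexing="ij"), -1).reshape(-1, 3)
            vals = (
                np.linalg.norm(centers[None] - grid[:, None], axis=2) + radii[None]
            ).max(axis=1)
            best = grid[int(np.argmin(vals))]
            half /= 2.0
        assert got.radius == pytest.approx(worst(best), abs=1e-3)

    @pytest.mark.parametrize("seed", range(5))
    def test_contains_every_ball(self, seed):
        spheres = random_spheres(15, seed + 10)
        s = minimum_enclosing_sphere(spheres)
        for b in spheres:
            assert np.linalg.norm(s.center - b.center) + b.radius <= s.radius + 1e-6


# ---------------------------------------------------------------------- pca


class TestPcaBoxExtents:
    CROSS = [
        Sphere([2, 0, 0], 0.0),
        Sphere([-2, 0, 0], 0.0),
        Sphere([0, 1, 0], 0.0),
        Sphere([0, -1, 0], 0.0),
    ]

    def test_axis_aligned_points(self):
        e = pca_box_extents(self.CROSS, include_radii=False)
        assert (e.L1, e.L2, e.L3) == pytest.approx((4.0, 2.0, 0.0), abs=1e-9)

    def test_radii_extend_extents_by_diameter(self):
        balls = [Sphere(s.center, 0.5) for s in self.CROSS]
        e = pca_box_extents(balls, include_radii=True)
        assert (e.L1, e.L2, e.L3) == pytest.approx((5.0, 3.0, 1.0), abs=1e-9)

    def test_rotation_invariance(self, rigid_motion):
        rng = np.random.default_rng(3)
        balls = [
            Sphere(rng.uniform(-4, 4, 3), rng.uniform(0.5, 1.5)) for _ in range(30)
        ]
        ref = pca_box_extents(balls)
        for rot, t in rigid_motion:
            moved = [Sphere(rot @ b.center + t, b.radius) for b in balls]
            e = pca_box_extents(moved)
            assert np.allclose(
                [e.L1, e.L2, e.L3], [ref.L1, ref.L2, ref.L3], atol=1e-6
            )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pca_box_extents([])


# ------------------------------------------------------------------- volume


class TestUnionVolume:
    def test_single_ball_closed_form(self):
        v, _ = union_volume([Sphere([0, 0, 0], 1.0)], resolution=0.05)
        assert v == pytest.approx(FOUR_THIRDS_PI, rel=0.005)

    def test_two_ball_lens_closed_form(self):
        # r = 1, d = 1: 2*(4pi/3) - pi*(4r+d)(2r-d)^2/12
        expect = 2 * FOUR_THIRDS_PI - math.pi * 5.0 * 1.0 / 12.0
        assert expect == pytest.approx(7.06858, abs=1e-5)
        v, _ = union_volume(
            [Sphere([0, 0, 0], 1.0), Sphere([1, 0, 0], 1.0)], resolution=0.05
        )
        assert v == pytest.approx(expect, rel=0.005)

    def test_disjoint_balls_add(self):
        v, _ = union_volume(
            [Sphere([0, 0, 0], 1.0), Sphere([2.5, 0, 0], 1.0)], resolution=0.05
        )
        assert v == pytest.approx(2 * FOUR_THIRDS_PI, rel=0.005)

    def test_grid_and_montecarlo_agree(self):
        balls = random_spheres(8, seed=4, box=3.0, rmax=1.5)
        vg, _ = union_volume(balls, resolution=0.05)
        vm, se = union_volume(balls, method="montecarlo", samples=400_000, seed=1)
        assert vm == pytest.approx(vg, abs=max(5 * se, 0.01 * vg))

    def test_richardson_refinement_shrinks_error(self):
        balls = [Sphere([0, 0, 0], 1.0), Sphere([1, 0, 0], 1.0)]
        _, err_coarse = union_volume(balls, resolution=0.2)
        _, err_fine = union_volume(balls, resolution=0.05)
        assert err_fine < err_coarse

    @pytest.mark.parametrize("seed", range(3))
    def test_bounded_by_largest_ball_and_sum(self, seed):
        balls = random_spheres(10, seed + 20, box=2.5)
        v, _ = union_volume(balls, resolution=0.1)
        biggest = max(FOUR_THIRDS_PI * b.radius**3 for b in balls)
        total = sum(FOUR_THIRDS_PI * b.radius**3 for b in balls)
        assert biggest * 0.99 <= v <= total * 1.01

    def test_bad_arguments(self):
        with pytest.raises(ValueError):
            union_volume([Sphere([0, 0, 0], 1.0)], resolution=0.0)
        with pytest.raises(ValueError):
            union_volume([], resolution=0.1)


class TestEqualVolumeRadius:
    def test_unit_sphere(self):
        assert equal_volume_radius(FOUR_THIRDS_PI) == pytest.approx(1.0, abs=1e-12)

    def test_zero(self):
        assert equal_volume_radius(0.0) == 0.0

    def test_lens_volume(self):
        assert equal_volume_radius(7.06858) == pytest.approx(1.1905, abs=1e-4)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            equal_volume_radius(-1.0)

    @settings(max_examples=50, derandomize=True)
    @given(
        v1=st.floats(0.0, 1e4, allow_nan=False),
        dv=st.floats(1e-6, 1e3, allow_nan=False),
    )
    def test_strictly_increasing(self, v1, dv):
        assert equal_volume_radius(v1 + dv) > equal_volume_radius(v1)

    @pytest.mark.parametrize("seed", range(3))
    def test_union_radius_below_enclosing_radius(self, seed):
        balls = random_spheres(12, seed + 30, box=3.0)
        v, _ = union_volume(balls, resolution=0.1)
        assert equal_volume_radius(v) <= minimum_enclosing_sphere(balls).radius + 1e-6


# ------------------------------------------------------------------ tangent


class TestTangentProbeCenters:
    def equilateral(self, side=4.0):
        h = side * math.sin(math.pi / 3.0)
        return (
            Sphere([0, 0, 0], 1.0),
            Sphere([side, 0, 0], 1.0),
            Sphere([side / 2.0, h, 0], 1.0),
        )

    def test_equilateral_mirror_pair(self):
        # circumradius 4/sqrt(3); h^2 = (1 + beta)^2 - R^2 with beta = 1.5
        sols = tangent_probe_centers(*self.equilateral(), beta=1.5)
        assert len(sols) == 2
        zs = sorted(p[2] for p in sols)
        assert zs == pytest.approx([-0.9574, 0.9574], abs=1e-4)
        assert np.allclose(sols[0][:2], sols[1][:2], atol=1e-9)

    def test_infeasible_when_probe_too_small(self):
        # (1 + 1.0) < circumradius 4/sqrt(3): no tangent sphere exists
        assert tangent_probe_centers(*self.equilateral(), beta=1.0) == []

    def test_tangency_system_satisfied_to_high_precision(self):
        spheres = random_spheres(3, seed=7, box=2.0, rmax=1.2)
        for beta in (0.5, 1.4, 3.0):
            for p in tangent_probe_centers(*spheres, beta=beta):
                for s in spheres:
                    d = np.linalg.norm(p - s.center)
                    assert d == pytest.approx(s.radius + beta, rel=1e-9, abs=1e-9)

    def test_collinear_rejected(self):
        with pytest.raises(DegenerateInputError):
            tangent_probe_centers(
                Sphere([0, 0, 0], 1.0),
                Sphere([2, 0, 0], 1.0),
                Sphere([4, 0, 0], 1.0),
                beta=1.0,
            )

    def test_rigid_motion_covariance(self, rigid_motion):
        spheres = self.equilateral()
        ref = tangent_probe_centers(*spheres, beta=1.5)
        for rot, t in rigid_motion:
            moved = [Sphere(rot @ s.center + t, s.radius) for s in spheres]
            got = tangent_probe_centers(*moved, beta=1.5)
            expect = {tuple(np.round(rot @ p + t, 8)) for p in ref}
            assert {tuple(np.round(p, 8)) for p in got} == expect
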