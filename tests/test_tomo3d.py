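"""3D micromorphology: radial profiles, porosity, skeletons, clustering."""

import numpy as np
import pytest

from pelletmorph import tomo3d
from pelletmorph.phantom import (
    PelletSpec,
    census_pellet_spec,
    grow_pellet,
    voxelize,
)
from pelletmorph.tomo3d import (
    PelletVolume,
    binarize,
    cluster_spores,
    estimate_hyphal_diameter,
    pellet_envelope,
    porosity,
    radial_solid_fraction,
    skeleton_metrics,
    skeletonize_volume,
    volume_equivalent_diameter,
)

from conftest import dbscan_oracle, make_ball, make_tube, make_y_phantom


class TestBinarize:
    def test_binary_input_passes_through(self):
        grid = make_ball(20.0).grid
        vol = binarize(grid.astype(np.uint8), 1.0, min_component_voxels=1)
        np.testing.assert_array_equal(vol.grid, grid)

    def test_noisy_ball_recovers_mask(self):
        truth = make_ball(30.0).grid
        rng = np.random.default_rng(0)
        gray = np.where(truth, 1.0, 0.0) + rng.normal(scale=0.10, size=truth.shape)
        vol = binarize(gray, 1.0)
        agreement = (vol.grid == truth).mean()
        assert agreement >= 0.99

    def test_all_background_raises(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((20, 20, 20)), 1.0)


class TestRadialProfile:
    def test_solid_ball_closed_form(self, ball100):
        prof = radial_solid_fraction(ball100)
        # interior regions full, boundary shell intermediate
        np.testing.assert_allclose(prof.shell_inner_radii, [0, 50, 65, 80, 95])
        assert np.all(prof.solid_fraction_per_shell[:-1] > 0.999)
        assert 0.05 < prof.solid_fraction_per_shell[-1] < 0.95

    def test_hollow_shell_band_indicator(self):
        n = 170
        x, y, z = np.indices((n, n, n))
        c = (n - 1) / 2
        r = np.sqrt((x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2)
        vol = PelletVolume((r >= 60) & (r < 75), 1.0)
        prof = radial_solid_fraction(vol)
        # core empty; the [65, 80) shell mostly solid; shell [50,65) partial
        assert prof.solid_fraction_per_shell[0] == 0.0
        idx = {int(r0): f for r0, f in zip(prof.shell_inner_radii, prof.solid_fraction_per_shell)}
        assert idx[65] > 0.6
        assert idx[0] == 0.0

    def test_uniform_random_fill_within_binomial_bounds(self):
        rng = np.random.default_rng(3)
        p = 0.1
        vol = PelletVolume(rng.random((90, 90, 90)) < p, 1.0)
        prof = radial_solid_fraction(vol)
        for frac, ntot in zip(prof.solid_fraction_per_shell, prof.voxels_per_shell):
            sd = np.sqrt(p * (1 - p) / ntot)
            assert abs(frac - p) <= 3 * sd + 1e-9

    def test_volume_weighted_mean_equals_global_fraction(self):
        rng = np.random.default_rng(5)
        vol = PelletVolume(rng.random((70, 70, 70)) < 0.3, 1.0)
        prof = radial_solid_fraction(vol)
        weighted = np.sum(
            prof.solid_fraction_per_shell * prof.voxels_per_shell
        ) / np.sum(prof.voxels_per_shell)
        assert weighted == pytest.approx(vol.grid.mean())

    def test_fractions_bounded(self, ball100):
        prof = radial_solid_fraction(ball100)
        assert np.all(prof.solid_fraction_per_shell >= 0)
        assert np.all(prof.solid_fraction_per_shell <= 1)


class TestEnvelopeAndPorosity:
    def test_solid_ball_porosity_near_zero(self, ball100):
        assert porosity(ball100) <= 0.01

    def test_ball_volume_equivalent_diameter(self, ball100):
        assert volume_equivalent_diameter(ball100) == pytest.approx(200.0, abs=1.0)

    def test_collinear_solid_flags_degenerate(self):
        grid = np.zeros((5, 5, 60), dtype=bool)
        grid[2, 2, 5:55] = True
        env = pellet_envelope(PelletVolume(grid, 1.0))
        assert env.degenerate

    def test_porosity_plus_envelope_fraction_is_one(self):
        vol = voxelize(grow_pellet(census_pellet_spec(1)), 1.0)
        env = pellet_envelope(vol)
        assert porosity(vol, env) + vol.n_solid / env.n_voxels_inside == pytest.approx(1.0)

    def test_fused_balls_match_monte_carlo_hull(self):
        """Envelope volume of two overlapping balls vs MC union-hull oracle."""
        n = 140
        x, y, z = np.indices((n, n, n))
        c1 = np.array([45, 70, 70])
        c2 = np.array([95, 70, 70])
        g = (((x - c1[0]) ** 2 + (y - c1[1]) ** 2 + (z - c1[2]) ** 2) <= 50**2) | (
            ((x - c2[0]) ** 2 + (y - c2[1]) ** 2 + (z - c2[2]) ** 2) <= 50**2
        )
        vol = PelletVolume(g, 1.0)
        env = pellet_envelope(vol)
        # MC oracle: hull of two spheres = union + the waist band; sample points
        rng = np.random.default_rng(0)
        pts = rng.uniform([0, 15, 15], [140, 125, 125], size=(200000, 3))
        in1 = ((pts - c1) ** 2).sum(1) <= 50**2
        in2 = ((pts - c2) ** 2).sum(1) <= 50**2
        # hull of two equal spheres: union plus the conical frustum between
        # tangent planes — approximate by convex combination test
        lam = np.clip(((pts - c1) @ (c2 - c1)) / ((c2 - c1) ** 2).sum(), 0, 1)
        axis_pt = c1 + lam[:, None] * (c2 - c1)
        in_tube = ((pts - axis_pt) ** 2).sum(1) <= 50**2
        frac = (in1 | in2 | in_tube).mean()
        mc_volume = frac * (140 * 110 * 110)
        assert env.volume == pytest.approx(mc_volume, rel=0.02)


class TestSkeleton:
    def test_straight_tube_census_and_length(self):
        vol = make_tube(100.0, 1.5, 1.0)
        sg = skeletonize_volume(vol)
        total_m, tips, branch, abl = skeleton_metrics(sg)
        assert (tips, branch) == (2, 0)
        assert sg.n_edges == 1
        assert total_m * 1e6 == pytest.approx(100.0, abs=5.0)

    def test_y_phantom_census(self):
        vol = make_y_phantom(arm=60.0)
        sg = skeletonize_volume(vol)
        assert sg.n_tips == 3
        assert sg.n_branch_points == 1
        total_m, _, _, abl = skeleton_metrics(sg)
        assert abl == pytest.approx(60.0, abs=4.0)
        assert total_m * 1e6 == pytest.approx(180.0, rel=0.05)

    def test_empty_volume_gives_empty_graph(self):
        sg = skeletonize_volume(PelletVolume(np.zeros((10, 10, 10), bool), 1.0))
        assert skeleton_metrics(sg) == (0.0, 0, 0, None)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_voxelized_pellet_census_exact(self, seed):
        pellet = grow_pellet(census_pellet_spec(seed))
        vol = voxelize(pellet, 1.0)
        sg = skeletonize_volume(vol)
        total_m, tips, branch, _ = skeleton_metrics(sg)
        assert (tips, branch) == pellet.census()
        assert total_m == pytest.approx(pellet.true_total_length, rel=0.08)

    def test_forest_of_disjoint_tubes(self):
        """k disjoint straight tubes → 2k tips, 0 branch points."""
        k = 3
        grid = np.zeros((20 * k, 20, 120), dtype=bool)
        x, y, z = np.indices(grid.shape)
        for i in range(k):
            grid |= (
                ((x - (10 + 20 * i)) ** 2 + (y - 10) ** 2 <= 1.5**2)
                & (z >= 10)
                & (z < 110)
            )
        sg = skeletonize_volume(PelletVolume(grid, 1.0))
        assert sg.n_tips == 2 * k
        assert sg.n_branch_points == 0

    def test_metrics_invariant_under_right_angle_rotation(self):
        pellet = grow_pellet(census_pellet_spec(2))
        vol = voxelize(pellet, 1.0)
        rot = PelletVolume(np.rot90(vol.grid, k=1, axes=(0, 2)).copy(), 1.0)
        a = skeleton_metrics(skeletonize_volume(vol))
        b = skeleton_metrics(skeletonize_volume(rot))
        assert a[1:3] == b[1:3]  # census strictly invariant
        # thinning is only approximately orientation-independent in length
        assert a[0] == pytest.approx(b[0], rel=0.08)
        assert porosity(vol) == pytest.approx(porosity(rot), abs=0.005)


class TestHyphalDiameter:
    @pytest.mark.parametrize(
        "radius,voxel,expected",
        [(1.5, 0.5, 3.0), (3.0, 1.0, 6.0)],
    )
    def test_tube_diameter_from_distance_transform(self, radius, voxel, expected):
        vol = make_tube(100.0, radius, voxel)
        sg = skeletonize_volume(vol)
        d = estimate_hyphal_diameter(vol, sg)
        assert d == pytest.approx(expected, abs=0.5)

    def test_pellet_population_diameter(self):
        vals = []
        for seed in range(3):
            pellet = grow_pellet(census_pellet_spec(seed))
            vol = voxelize(pellet, 1.0)
            sg = skeletonize_volume(vol)
            vals.append(estimate_hyphal_diameter(vol, sg))
        assert np.mean(vals) == pytest.approx(3.0, rel=0.15)


class TestClusterSpores:
    def test_two_blobs(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 5, (20, 3)), rng.normal(200, 5, (20, 3))])
        labels, k = cluster_spores(pts, eps=30, min_pts=3)
        assert k == 2
        assert (labels >= 0).all()

    def test_single_blob(self):
        rng = np.random.default_rng(1)
        _, k = cluster_spores(rng.normal(0, 5, (25, 3)), eps=30, min_pts=3)
        assert k == 1

    def test_isolated_point_is_noise(self):
        pts = np.array([[0.0, 0.0, 0.0]])
        labels, k = cluster_spores(pts, eps=10, min_pts=3)
        assert k == 0 and labels[0] == -1

    def test_empty_input(self):
        labels, k = cluster_spores(np.zeros((0, 3)), eps=10, min_pts=3)
        assert k == 0 and len(labels) == 0

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            cluster_spores(np.zeros((1, 3)), eps=0, min_pts=3)
        with pytest.raises(ValueError):
            cluster_spores(np.zeros((1, 3)), eps=5, min_pts=0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 200))
        k_blobs = int(rng.integers(1, 6))
        centres = rng.uniform(0, 400, size=(k_blobs, 3))
        pts = np.vstack(
            [c + rng.normal(0, rng.uniform(2, 15), size=(n // k_blobs + 1, 3)) for c in centres]
        )[:n]
        eps = float(rng.uniform(5, 40))
        min_pts = int(rng.integers(1, 6))
        core, labels_o, k_o = dbscan_oracle(pts, eps, min_pts)
        labels, k = cluster_spores(pts, eps=eps, min_pts=min_pts)
        assert k == k_o
        # identical noise set and identical core partition (up to relabeling)
        np.testing.assert_array_equal(labels == -1, labels_o == -1)
        for cid in range(k_o):
            members = np.flatnonzero((labels_o == cid) & core)
            assert len(set(labels[members])) == 1
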