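"""Crop box, plane fitting, normals, the hover filter, and samplers."""

import numpy as np
import pytest

from mixseedling.cloud import LabeledCloud
from mixseedling.preprocess import (
    BoxLimits,
    FilterParams,
    curvature_sample,
    estimate_ground_plane,
    estimate_normals,
    fit_plane_lsq,
    fps_downsample,
    neighborhood_filter,
    normalize_unit,
    passthrough_filter,
    remove_ground_and_tray,
    surface_variation,
)
from mixseedling.synth import NoiseSpec, SeedlingSpec, add_scene_background, add_sensor_noise, generate_seedling


class TestPassthrough:
    def test_center_kept_far_removed(self):
        cloud = LabeledCloud(points=np.array([[0, 0, 0], [1.0 + 0.35, 0, 0]]))
        out = passthrough_filter(cloud, BoxLimits(0.5, 0.5, 0.7))
        assert len(out) == 1
        np.testing.assert_array_equal(out.points[0], [0, 0, 0])

    def test_matches_bruteforce_box_test(self, rng):
        pts = rng.uniform(-0.6, 0.6, (1000, 3))
        cloud = LabeledCloud(points=pts, semantic=rng.integers(0, 2, 1000))
        box = BoxLimits(0.5, 0.5, 0.7)
        out = passthrough_filter(cloud, box)
        brute = [i for i, p in enumerate(pts)
                 if abs(p[0]) <= 0.25 and abs(p[1]) <= 0.25 and abs(p[2]) <= 0.35]
        np.testing.assert_array_equal(out.points, pts[brute])
        np.testing.assert_array_equal(out.semantic, cloud.semantic[brute])

    def test_empty_result_errors(self):
        cloud = LabeledCloud(points=np.full((3, 3), 5.0))
        with pytest.raises(ValueError, match="no plant"):
            passthrough_filter(cloud, BoxLimits())


class TestFitPlane:
    def test_exact_horizontal_plane(self, rng):
        pts = np.column_stack([rng.random(20), rng.random(20), np.full(20, 0.2)])
        plane = fit_plane_lsq(pts)
        np.testing.assert_allclose(plane.normal, [0, 0, 1], atol=1e-12)
        assert plane.offset == pytest.approx(-0.2, abs=1e-12)
        assert np.abs(plane.signed_distance(pts)).max() < 1e-12

    def test_three_points_zero_residual(self):
        pts = np.array([[0, 0, 0], [1, 0, 0.1], [0, 1, 0.3]])
        plane = fit_plane_lsq(pts)
        assert np.abs(plane.signed_distance(pts)).max() < 1e-12

    def test_noisy_plane_matches_eigen_oracle(self, rng):
        n_true = np.array([0.1, -0.2, 1.0])
        n_true /= np.linalg.norm(n_true)
        basis = np.linalg.svd(n_true[None])[2][1:]
        pts = rng.uniform(-1, 1, (500, 2)) @ basis + rng.normal(0, 1e-3, (500, 3))
        plane = fit_plane_lsq(pts)
        angle = np.degrees(np.arccos(abs(plane.normal @ n_true)))
        assert angle < 0.5
        # independent oracle: smallest eigenvector of the covariance
        q = pts - pts.mean(axis=0)
        evals, evecs = np.linalg.eigh(q.T @ q)
        oracle = evecs[:, 0] * np.sign(evecs[2, 0])
        assert abs(plane.normal @ oracle) > 1 - 1e-9

    def test_collinear_rejected(self):
        pts = np.outer(np.arange(5.0), [1, 1, 0])
        with pytest.raises(ValueError, match="degenerate"):
            fit_plane_lsq(pts)


@pytest.fixture(scope="module")
def scene():
    plant = generate_seedling(SeedlingSpec(n_leaves=2, seed=0))
    return plant, add_scene_background(plant, tray_height=0.11, seed=0)


class TestGroundTrayRemoval:

    def test_background_fully_removed(self, scene):
        plant, full = scene
        plane = estimate_ground_plane(full)
        out = remove_ground_and_tray(full, plane, cut_offset=0.12)
        assert (out.semantic != -1).all()

    def test_plant_above_plane_unchanged(self, scene):
        plant, full = scene
        plane = estimate_ground_plane(full)
        out = remove_ground_and_tray(full, plane, cut_offset=0.12)
        assert (out.semantic >= 0).sum() == len(plant)

    def test_no_ground_points_identity(self, scene):
        plant, _ = scene
        plane = fit_plane_lsq(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]]))
        out = remove_ground_and_tray(plant, plane, cut_offset=0.12)
        assert len(out) == len(plant)

    def test_out_of_band_cut_warns_not_errors(self, scene):
        plant, _ = scene
        plane = fit_plane_lsq(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]]))
        with pytest.warns(UserWarning, match="0.11-0.13"):
            remove_ground_and_tray(plant, plane, cut_offset=0.2)


class TestEstimateNormals:
    def test_flat_patch_normals_vertical(self, rng):
        pts = np.column_stack([rng.random(300), rng.random(300), np.zeros(300)])
        normals, degen = estimate_normals(LabeledCloud(points=pts), N=12)
        assert not degen.any()
        np.testing.assert_allclose(normals, np.tile([0, 0, 1.0], (300, 1)), atol=1e-6)

    def test_jittered_vertical_line_normals_horizontal(self, rng):
        pts = np.column_stack([rng.normal(0, 1e-6, 100), rng.normal(0, 1e-6, 100),
                               np.linspace(0, 0.1, 100)])
        normals, _ = estimate_normals(LabeledCloud(points=pts), N=8)
        angle_from_z = np.degrees(np.arccos(np.clip(np.abs(normals[:, 2]), 0, 1)))
        assert (angle_from_z > 89.0).all()

    def test_sphere_normals_radial(self, rng):
        v = rng.standard_normal((2000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        normals, _ = estimate_normals(LabeledCloud(points=v), N=12)
        cosang = np.abs(np.einsum("ij,ij->i", normals, v))
        angles = np.degrees(np.arccos(np.clip(cosang, 0, 1)))
        # moderate random density: the bulk is within 5 deg of radial
        assert np.percentile(angles, 95) < 5.0
        assert angles.mean() < 2.5


class TestNeighborhoodFilter:
    def test_isolated_outlier_removed(self, rng):
        d = 0.0034
        patch = np.column_stack([rng.random(200) * 0.02, rng.random(200) * 0.02, np.zeros(200)])
        outlier = np.array([[0.01, 0.01, 10 * d + 0.02]])
        cloud = LabeledCloud(points=np.vstack([patch, outlier]))
        kept, removed = neighborhood_filter(cloud, FilterParams())
        assert removed[-1]

    def test_dense_horizontal_patch_kept(self, rng):
        pts = np.column_stack([rng.random(500) * 0.02, rng.random(500) * 0.02, np.zeros(500)])
        kept, removed = neighborhood_filter(LabeledCloud(points=pts), FilterParams())
        assert not removed.any()

    def test_hover_chain_removed(self, rng):
        """A constructed vertical chain above a dense patch is deleted."""
        patch = np.column_stack([rng.random(800) * 0.04, rng.random(800) * 0.04,
                                 rng.normal(0, 1e-4, 800)])
        chain_z = np.linspace(0.01, 0.09, 12)
        chain = np.column_stack([np.full(12, 0.02), np.full(12, 0.02), chain_z])
        cloud = LabeledCloud(points=np.vstack([patch, chain]))
        _, removed = neighborhood_filter(cloud, FilterParams())
        assert removed[-12:].mean() >= 0.95
        # per-point recomputation: chain spacing alone exceeds d
        spacing = np.diff(chain_z).mean()
        assert spacing >= FilterParams().d

    def test_too_small_cloud_errors(self):
        with pytest.raises(ValueError):
            neighborhood_filter(LabeledCloud(points=np.eye(3)), FilterParams(N=12))

    def test_idempotent_on_flat_patch(self, rng):
        pts = np.column_stack([rng.random(500) * 0.02, rng.random(500) * 0.02, np.zeros(500)])
        kept1, _ = neighborhood_filter(LabeledCloud(points=pts), FilterParams())
        kept2, removed2 = neighborhood_filter(kept1, FilterParams())
        assert not removed2.any()


class TestFilterEfficacyInvariant:
    def test_composed_pipeline_leaves_only_plant(self):
        plant = generate_seedling(SeedlingSpec(n_leaves=3, seed=11))
        scene = add_sensor_noise(add_scene_background(plant, seed=11), NoiseSpec(seed=11))
        crop = passthrough_filter(scene, BoxLimits())
        cut = remove_ground_and_tray(crop, estimate_ground_plane(crop), 0.12)
        kept, removed = neighborhood_filter(cut, FilterParams())
        noise = cut.noise_mask
        assert removed[noise].mean() >= 0.95
        assert removed[cut.semantic >= 0].mean() <= 0.05
        assert (kept.semantic >= 0).mean() > 0.99


class TestNormalizeUnit:
    def test_two_point_example(self):
        cloud = LabeledCloud(points=np.array([[0, 0, 0], [2.0, 0, 0]]))
        out, t = normalize_unit(cloud)
        np.testing.assert_allclose(out.points, [[-1, 0, 0], [1, 0, 0]])
        assert t.scale == 1.0

    def test_round_trip_inverse(self, rng):
        pts = rng.standard_normal((50, 3)) * 7 + 3
        out, t = normalize_unit(LabeledCloud(points=pts))
        np.testing.assert_allclose(t.inverse(out.points), pts, atol=1e-9)

    def test_max_abs_coordinate_is_one(self, rng):
        out, _ = normalize_unit(LabeledCloud(points=rng.standard_normal((100, 3))))
        assert np.abs(out.points).max() == pytest.approx(1.0, abs=1e-12)

    def test_zero_extent_errors(self):
        with pytest.raises(ValueError):
            normalize_unit(LabeledCloud(points=np.zeros((4, 3))))


class TestFPS:
    def test_n_equals_total_is_permutation(self, rng):
        pts = rng.standard_normal((30, 3))
        out = fps_downsample(LabeledCloud(points=pts), 30)
        assert {tuple(p) for p in out.points} == {tuple(p) for p in pts}

    def test_segment_farthest_logic(self):
        cloud = LabeledCloud(points=np.array([[0.0, 0, 0], [0.5, 0, 0], [1.0, 0, 0]]))
        # default start = farthest from centroid = an endpoint; next = other endpoint
        out = fps_downsample(cloud, 2)
        xs = sorted(out.points[:, 0])
        assert xs == [0.0, 1.0]

    def test_better_spread_than_random_sampling(self, rng):
        """FPS min pairwise distance beats uniform sampling in >= 95% of trials."""
        pts = rng.random((512, 3))
        cloud = LabeledCloud(points=pts)
        fps_pts = fps_downsample(cloud, 16).points
        def min_pair(p):
            d = np.linalg.norm(p[:, None] - p[None], axis=2)
            return d[np.triu_indices(len(p), 1)].min()
        fps_min = min_pair(fps_pts)
        wins = sum(fps_min >= min_pair(pts[rng.choice(512, 16, replace=False)])
                   for _ in range(100))
        assert wins >= 95

    def test_oversample_errors(self):
        with pytest.raises(ValueError):
            fps_downsample(LabeledCloud(points=np.eye(3)), 4)


class TestCurvatureSample:
    def test_flat_plane_equals_fps_fallback(self, rng):
        g = np.linspace(0, 1, 20)
        xx, yy = np.meshgrid(g, g)
        pts = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(400)])
        cloud = LabeledCloud(points=pts)
        idx = curvature_sample(cloud, 16)
        fps = fps_downsample(cloud, 16)
        assert {tuple(p) for p in pts[idx]} == {tuple(p) for p in fps.points}

    def test_crease_points_rank_highest(self):
        g = np.linspace(-1, 1, 40)
        xx, yy = np.meshgrid(g, g)
        pts = np.column_stack([xx.ravel(), yy.ravel(), np.abs(xx.ravel()) * 0.5])
        s = surface_variation(pts, k=16)
        crease = np.abs(pts[:, 0]) < 0.03
        assert s[crease].mean() > 5 * s[~crease & (np.abs(pts[:, 0]) > 0.2)].mean()
        # the first picks (before spatial suppression kicks in) sit on the crease
        idx = curvature_sample(LabeledCloud(points=pts), 8)
        assert (np.abs(pts[idx[:2], 0]) < 0.06).all()

    def test_n_equals_total(self, rng):
        pts = rng.standard_normal((25, 3))
        np.testing.assert_array_equal(curvature_sample(LabeledCloud(points=pts), 25), np.arange(25))

    def test_deterministic(self, two_leaf_seedling):
        a = curvature_sample(two_leaf_seedling, 64)
        b = curvature_sample(two_leaf_seedling, 64)
        np.testing.assert_array_equal(a, b)
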