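"""ROI boxes, region labels, sampling, features, augmentation, manual crop."""

import numpy as np
import pytest

from pelvimark.geometry import LANDMARK_NAMES, LandmarkSet, PointCloud
from pelvimark.preprocessing import (
    AugmentationConfig,
    InsufficientPointsError,
    LabelVector,
    ROIBox,
    augment,
    build_point_features,
    downsample_uniform,
    label_landmark_regions,
    label_points_in_box,
    roi_box_from_markers,
    simulate_manual_crop,
)


class TestRoiBox:
    def test_margin_arithmetic(self):
        lms = LandmarkSet(PSIS_L=(-50, 0, 0), PSIS_R=(60, 10, 20))
        box = roi_box_from_markers(lms, 100.0)
        np.testing.assert_allclose(box.bounds[0], [-150.0, 160.0])
        np.testing.assert_allclose(box.bounds[1], [-100.0, 110.0])
        np.testing.assert_allclose(box.bounds[2], [-100.0, 120.0])

    def test_single_marker_gives_cube(self):
        box = roi_box_from_markers(LandmarkSet(L4=(0, 0, 0)), 100.0)
        np.testing.assert_allclose(box.bounds, [[-100, 100]] * 3)

    def test_zero_margin_is_marker_bbox(self):
        lms = LandmarkSet(PSIS_L=(-50, -1, -2), PSIS_R=(60, 1, 2))
        with pytest.raises(ValueError):
            # zero-margin box around two markers is degenerate only if an
            # axis has zero extent; here all extents are positive
            ROIBox(np.array([[0, 0], [0, 1], [0, 1]]))
        box = roi_box_from_markers(lms, 0.0)
        np.testing.assert_allclose(box.bounds[:, 0], [-50, -1, -2])
        np.testing.assert_allclose(box.bounds[:, 1], [60, 1, 2])

    def test_translation_equivariance(self, rng):
        lms = LandmarkSet(PSIS_L=(-40, 0, 0), PSIS_R=(40, 5, 2), L4=(0, 70, 1))
        v = rng.normal(scale=30, size=3)
        moved = LandmarkSet({n: c + v for n, c in lms.items()})
        b0 = roi_box_from_markers(lms)
        b1 = roi_box_from_markers(moved)
        np.testing.assert_allclose(b1.bounds, b0.bounds + v[:, None], atol=1e-12)

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            roi_box_from_markers(LandmarkSet())


class TestBoxLabeling:
    def test_all_inside(self):
        cloud = PointCloud(np.zeros((5, 3)))
        box = ROIBox(np.array([[-1, 1], [-1, 1], [-1, 1]]))
        assert label_points_in_box(cloud, box).labels.tolist() == [1] * 5

    def test_corner_point_is_inside(self):
        cloud = PointCloud([[1.0, 1.0, 1.0]])
        box = ROIBox(np.array([[-1, 1], [-1, 1], [-1, 1]]))
        assert label_points_in_box(cloud, box).labels[0] == 1

    def test_matches_per_axis_interval_oracle(self, rng):
        pts = rng.uniform(-2, 2, size=(1000, 3))
        box = ROIBox(np.array([[-1.0, 0.5], [-0.3, 1.2], [0.0, 1.9]]))
        got = label_points_in_box(PointCloud(pts), box).labels
        lo, hi = box.bounds[:, 0], box.bounds[:, 1]
        expect = np.array(
            [int(all(lo[a] <= p[a] <= hi[a] for a in range(3))) for p in pts]
        )
        np.testing.assert_array_equal(got, expect)


class TestLandmarkRegionLabeling:
    def test_point_just_inside_radius(self):
        lms = LandmarkSet(PSIS_L=(0, 0, 0))
        cloud = PointCloud([[9.9, 0, 0]])
        assert label_landmark_regions(cloud, lms, 10.0).labels[0] == 1

    def test_point_outside_radius_is_background(self, canonical_landmarks):
        cloud = PointCloud([[500.0, 500.0, 500.0]])
        assert label_landmark_regions(cloud, canonical_landmarks, 10.0).labels[0] == 0

    def test_boundary_is_closed(self):
        lms = LandmarkSet(L1=(0, 0, 0))
        cloud = PointCloud([[10.0, 0, 0], [10.0 + 1e-9, 0, 0]])
        labels = label_landmark_regions(cloud, lms, 10.0).labels
        assert labels.tolist() == [5, 0]

    def test_nearest_marker_wins_tie(self):
        lms = LandmarkSet(L1=(0, 0, 0), L4=(14, 0, 0))
        cloud = PointCloud([[6.0, 0, 0], [8.0, 0, 0]])
        labels = label_landmark_regions(cloud, lms, 10.0).labels
        assert labels.tolist() == [5, 6]

    def test_matches_distance_oracle(self, rng, canonical_landmarks):
        pts = rng.uniform(-150, 200, size=(1000, 3))
        got = label_landmark_regions(PointCloud(pts), canonical_landmarks, 10.0).labels
        for i, p in enumerate(pts):
            d = [
                np.linalg.norm(p - canonical_landmarks[n]) if n in canonical_landmarks else np.inf
                for n in LANDMARK_NAMES
            ]
            k = int(np.argmin(d))
            expect = k + 1 if d[k] <= 10.0 else 0
            assert got[i] == expect

    def test_label_class_count_is_seven(self, random_cloud, canonical_landmarks):
        lv = label_landmark_regions(random_cloud, canonical_landmarks)
        assert lv.n_classes == 7
        assert lv.kind == "landmark"


class TestDownsample:
    def test_output_is_subset_without_replacement(self, rng):
        cloud = PointCloud(rng.normal(size=(300, 3)))
        out = downsample_uniform(cloud, 100, seed=5)
        assert out.n_points == 100
        # every output point appears in the input
        joined = {tuple(p) for p in cloud.positions}
        assert all(tuple(p) in joined for p in out.positions)
        assert len({tuple(p) for p in out.positions}) == 100

    def test_n_equals_size_is_permutation(self, rng):
        cloud = PointCloud(rng.normal(size=(50, 3)))
        out = downsample_uniform(cloud, 50, seed=0)
        assert sorted(map(tuple, out.positions)) == sorted(map(tuple, cloud.positions))

    def test_deterministic_for_fixed_seed(self, rng):
        cloud = PointCloud(rng.normal(size=(200, 3)))
        a = downsample_uniform(cloud, 64, seed=9)
        b = downsample_uniform(cloud, 64, seed=9)
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_labels_subset_consistently(self, rng):
        pts = rng.normal(size=(200, 3))
        labels = LabelVector((pts[:, 0] > 0).astype(int), 2)
        cloud, sub = downsample_uniform(PointCloud(pts), 80, seed=3, labels=labels)
        np.testing.assert_array_equal(sub.labels, (cloud.positions[:, 0] > 0).astype(int))

    def test_insufficient_points_raises(self, rng):
        with pytest.raises(InsufficientPointsError):
            downsample_uniform(PointCloud(rng.normal(size=(10, 3))), 11, seed=0)


class TestPointFeatures:
    def test_minmax_formula(self):
        pts = np.zeros((3, 3))
        pts[:, 0] = [0.0, 25.0, 100.0]
        pts[:, 1] = [0.0, 5.0, 10.0]
        pts[:, 2] = [1.0, 1.0, 2.0]
        out = build_point_features(PointCloud(pts))
        np.testing.assert_allclose(out.features[:, :3], pts)
        np.testing.assert_allclose(out.features[1, 3:], [0.25, 0.5, 0.0])

    def test_degenerate_axis_maps_to_half(self):
        out = build_point_features(PointCloud(np.ones((4, 3))))
        np.testing.assert_allclose(out.features[:, 3:], 0.5)

    def test_normalized_channels_within_unit_interval(self, random_cloud):
        out = build_point_features(random_cloud)
        assert out.features[:, 3:].min() >= 0.0
        assert out.features[:, 3:].max() <= 1.0


class TestAugment:
    def test_factor_count(self, random_cloud):
        cfg = AugmentationConfig(factor=20, seed=1)
        assert len(augment(random_cloud, None, None, cfg)) == 20

    def test_zero_range_gives_centroid_translated_copies(self, random_cloud):
        cfg = AugmentationConfig(rotation_range_deg=0.0, factor=3, seed=1)
        centroid = random_cloud.positions.mean(axis=0)
        for s in augment(random_cloud, None, None, cfg):
            np.testing.assert_allclose(
                s.cloud.positions, random_cloud.positions - centroid, atol=1e-12
            )
            np.testing.assert_allclose(s.rotation, np.eye(3), atol=1e-12)

    def test_recorded_rotation_inverts_exactly(self, random_cloud, canonical_landmarks):
        cfg = AugmentationConfig(factor=5, seed=7)
        centroid = random_cloud.positions.mean(axis=0)
        for s in augment(random_cloud, None, canonical_landmarks, cfg):
            restored = s.cloud.positions @ s.rotation + centroid
            np.testing.assert_allclose(restored, random_cloud.positions, atol=1e-9)

    def test_labels_carried_and_landmarks_cotransformed(self, random_cloud, canonical_landmarks):
        labels = LabelVector(np.zeros(random_cloud.n_points, dtype=int), 2)
        cfg = AugmentationConfig(factor=2, seed=3)
        centroid = random_cloud.positions.mean(axis=0)
        for s in augment(random_cloud, labels, canonical_landmarks, cfg):
            assert s.labels is labels
            # landmarks undergo the same rigid motion as the cloud
            expect = s.rotation @ (canonical_landmarks["L4"] - centroid)
            np.testing.assert_allclose(s.landmarks["L4"], expect, atol=1e-9)

    def test_rigid_distances_preserved(self, random_cloud):
        cfg = AugmentationConfig(factor=2, seed=11)
        d0 = np.linalg.norm(
            random_cloud.positions[:50, None] - random_cloud.positions[None, :50], axis=-1
        )
        for s in augment(random_cloud, None, None, cfg):
            d1 = np.linalg.norm(
                s.cloud.positions[:50, None] - s.cloud.positions[None, :50], axis=-1
            )
            assert np.abs(d0 - d1).max() < 1e-9

    def test_angles_bounded_by_range(self, random_cloud):
        from pelvimark.geometry import euler_from_rotation

        cfg = AugmentationConfig(rotation_range_deg=20.0, factor=50, seed=2)
        for s in augment(random_cloud, None, None, cfg):
            # the recorded matrix factors into per-axis angles within range
            e = euler_from_rotation(s.rotation)
            assert np.abs(e.as_array()).max() <= np.deg2rad(20.0) + 1e-9


class TestManualCrop:
    def test_degenerate_interval_equals_fixed_margin(self, small_scan):
        cloud, lms = small_scan
        crop = simulate_manual_crop(cloud, lms, lo=100.0, hi=100.0, seed=0)
        from pelvimark.preprocessing import roi_box_from_markers

        box = roi_box_from_markers(lms, 100.0)
        expect = cloud.subset(box.contains(cloud.positions))
        np.testing.assert_array_equal(crop.positions, expect.positions)

    def test_offsets_within_range_over_seeds(self, small_scan):
        cloud, lms = small_scan
        pts = np.stack([lms[n] for n in lms])
        lo_b, hi_b = pts.min(axis=0), pts.max(axis=0)
        for seed in range(100):
            crop = simulate_manual_crop(cloud, lms, seed=seed)
            cmin = crop.positions.min(axis=0)
            cmax = crop.positions.max(axis=0)
            # crop bounds sit within [50, 150] mm outside the marker bbox
            assert np.all(cmin >= lo_b - 150.0 - 1e-9)
            assert np.all(cmax <= hi_b + 150.0 + 1e-9)

    def test_landmarks_always_inside_crop(self, small_scan):
        cloud, lms = small_scan
        for seed in range(20):
            crop = simulate_manual_crop(cloud, lms, seed=seed)
            lo = crop.positions.min(axis=0)
            hi = crop.positions.max(axis=0)
            for name in lms:
                assert np.all(lms[name] >= lo - 15.0) and np.all(lms[name] <= hi + 15.0)

    def test_deterministic_per_seed(self, small_scan):
        cloud, lms = small_scan
        a = simulate_manual_crop(cloud, lms, seed=5)
        b = simulate_manual_crop(cloud, lms, seed=5)
        np.testing.assert_array_equal(a.positions, b.positions)
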