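"""Rigid transforms, rotation representations and the canonical pelvic pose."""

import json

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pelvimark.geometry import (
    DegenerateGeometryError,
    EulerAngles,
    InvalidRotationError,
    LandmarkSet,
    MissingLandmarkError,
    PointCloud,
    RigidTransform,
    apply_transform,
    canonicalize_pose,
    euler_from_rotation,
    rotation_angle,
    rotation_from_euler,
    svd_project,
)


def random_rotation(rng) -> np.ndarray:
    return Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()


class TestApplyTransform:
    def test_identity_leaves_cloud_unchanged(self, random_cloud):
        out = apply_transform(random_cloud, RigidTransform.identity())
        np.testing.assert_array_equal(out.positions, random_cloud.positions)

    def test_pure_translation_moves_origin_point(self):
        cloud = PointCloud([[0.0, 0.0, 0.0]])
        out = apply_transform(cloud, RigidTransform(np.eye(3), [3.0, 4.0, 0.0]))
        np.testing.assert_allclose(out.positions[0], [3.0, 4.0, 0.0])

    def test_rigid_transform_preserves_pairwise_distances(self, rng):
        pts = rng.normal(scale=50.0, size=(50, 3))
        cloud = PointCloud(pts)
        t = RigidTransform(random_rotation(rng), rng.normal(scale=30.0, size=3))
        out = apply_transform(cloud, t)
        # brute-force pairwise-distance oracle
        d0 = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        d1 = np.linalg.norm(out.positions[:, None] - out.positions[None], axis=-1)
        assert np.abs(d0 - d1).max() < 1e-9

    def test_strict_flag_rejects_non_rotation(self, random_cloud):
        bad = RigidTransform(2.0 * np.eye(3), np.zeros(3))
        with pytest.raises(InvalidRotationError):
            apply_transform(random_cloud, bad, strict=True)

    def test_features_and_metadata_preserved(self, rng):
        cloud = PointCloud(
            rng.normal(size=(10, 3)), features=rng.normal(size=(10, 6)), subject_id="S1"
        )
        out = apply_transform(cloud, RigidTransform(np.eye(3), [1.0, 0.0, 0.0]))
        np.testing.assert_array_equal(out.features, cloud.features)
        assert out.subject_id == "S1"


class TestSvdProject:
    def test_idempotent_on_rotations(self, rng):
        for _ in range(20):
            R = random_rotation(rng)
            np.testing.assert_allclose(svd_project(R), R, atol=1e-9)

    def test_diagonal_scaling_projects_to_identity(self):
        np.testing.assert_allclose(svd_project(np.diag([2.0, 1.0, 1.0])), np.eye(3), atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_negative_det_input_beats_random_rotations(self, seed):
        """The projection minimizes Frobenius distance over a dense random
        sample of the rotation group, even for det < 0 inputs."""
        rng = np.random.default_rng(seed)
        M = rng.normal(size=(3, 3))
        if np.linalg.det(M) > 0:
            M[:, 0] *= -1.0
        R = svd_project(M)
        assert np.linalg.det(R) > 0
        d_star = np.linalg.norm(M - R)
        samples = Rotation.random(4000, random_state=seed).as_matrix()
        d_rand = np.linalg.norm(M - samples, axis=(1, 2)).min()
        assert d_star <= d_rand + 1e-9

    def test_rank_deficient_matrix_raises(self):
        M = np.outer([1.0, 0.0, 0.0], [1.0, 0.0, 0.0])
        with pytest.raises(DegenerateGeometryError):
            svd_project(M)

    def test_output_always_special_orthogonal(self, rng):
        for _ in range(200):
            R = svd_project(rng.normal(size=(3, 3)))
            assert np.linalg.norm(R.T @ R - np.eye(3)) < 1e-6
            assert abs(np.linalg.det(R) - 1.0) < 1e-6


class TestEulerConversions:
    def test_identity_gives_zero_angles(self):
        e = euler_from_rotation(np.eye(3))
        assert e.as_array() == pytest.approx([0.0, 0.0, 0.0])

    def test_single_axis_z_rotation(self):
        R = rotation_from_euler([0.0, 0.0, 0.1])
        e = euler_from_rotation(R)
        np.testing.assert_allclose(e.as_array(), [0.0, 0.0, 0.1], atol=1e-12)

    def test_round_trip_100_random_rotations(self, rng):
        worst = 0.0
        for _ in range(100):
            angles = rng.uniform(-np.pi, np.pi, 3)
            angles[1] = rng.uniform(-(np.pi / 2 - 0.01), np.pi / 2 - 0.01)
            R = rotation_from_euler(angles)
            back = rotation_from_euler(euler_from_rotation(R))
            worst = max(worst, np.abs(back - R).max())
        assert worst < 1e-8

    def test_matches_scipy_intrinsic_xyz(self, rng):
        angles = rng.uniform(-1.0, 1.0, 3)
        ours = rotation_from_euler(angles)
        ref = Rotation.from_euler("XYZ", angles).as_matrix()
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_gimbal_lock_tie_break_sets_tz_zero(self):
        R = rotation_from_euler([0.3, np.pi / 2, 0.2])
        e = euler_from_rotation(R)
        assert e.tz == 0.0
        np.testing.assert_allclose(rotation_from_euler(e), R, atol=1e-8)


class TestCanonicalizePose:
    def _check_canonical(self, lms: LandmarkSet, tol=1e-6):
        mid = 0.5 * (lms["PSIS_L"] + lms["PSIS_R"])
        assert np.abs(mid).max() < tol
        assert abs(lms["PSIS_L"][2] - lms["PSIS_R"][2]) < tol
        assert abs(lms["L4"][2]) < tol

    def test_already_canonical_gives_identity(self, canonical_landmarks):
        t = canonicalize_pose(canonical_landmarks)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t.translation, 0.0, atol=1e-9)

    def test_recovers_known_y_then_x_rotation(self, canonical_landmarks):
        Ry = rotation_from_euler([0.0, np.deg2rad(15.0), 0.0])
        Rx = rotation_from_euler([np.deg2rad(7.0), 0.0, 0.0])
        Q = Ry @ Rx
        shift = np.array([10.0, -20.0, 30.0])
        moved = LandmarkSet({n: Q @ v + shift for n, v in canonical_landmarks.items()})
        t = canonicalize_pose(moved)
        self._check_canonical(moved.transform(t))

    def test_100_seeded_general_transforms_recovered(self, canonical_landmarks):
        rng = np.random.default_rng(42)
        for _ in range(100):
            Q = random_rotation(rng) if rng.random() < 0.3 else rotation_from_euler(
                rng.uniform(-0.4, 0.4, 3)
            )
            shift = rng.normal(scale=50.0, size=3)
            moved = LandmarkSet(
                {n: Q @ v + shift for n, v in canonical_landmarks.items()}
            )
            try:
                t = canonicalize_pose(moved)
            except DegenerateGeometryError:
                continue  # fully random rotations may flip the pelvis upside down
            self._check_canonical(moved.transform(t), tol=1e-5)

    def test_psis_midpoint_maps_to_origin(self, small_scan):
        _, lms = small_scan
        t = canonicalize_pose(lms)
        out = lms.transform(t)
        mid = 0.5 * (out["PSIS_L"] + out["PSIS_R"])
        assert np.abs(mid).max() < 1e-6

    def test_idempotent(self, small_scan):
        _, lms = small_scan
        once = lms.transform(canonicalize_pose(lms))
        t2 = canonicalize_pose(once)
        np.testing.assert_allclose(t2.rotation, np.eye(3), atol=1e-6)
        np.testing.assert_allclose(t2.translation, 0.0, atol=1e-4)

    def test_missing_landmark_raises(self):
        with pytest.raises(MissingLandmarkError):
            canonicalize_pose(LandmarkSet(PSIS_L=(-40, 0, 0), PSIS_R=(40, 0, 0)))

    def test_coincident_psis_raises(self):
        lms = LandmarkSet(PSIS_L=(0, 0, 0), PSIS_R=(0, 0, 0), L4=(0, 70, 0))
        with pytest.raises(DegenerateGeometryError):
            canonicalize_pose(lms)

    def test_composition_order_translation_then_ry_then_rx(self, canonical_landmarks):
        """The recovered rotation factors exactly as Rx(beta) @ Ry(alpha)."""
        rng = np.random.default_rng(3)
        Q = rotation_from_euler([0.2, -0.3, 0.0])
        moved = LandmarkSet(
            {n: Q @ v + rng.normal(scale=20, size=3) for n, v in canonical_landmarks.items()}
        )
        t = canonicalize_pose(moved)
        e = euler_from_rotation(t.rotation)
        refit = rotation_from_euler([e.tx, 0, 0]) @ rotation_from_euler([0, e.ty, 0])
        np.testing.assert_allclose(refit, t.rotation, atol=1e-9)


class TestRigidTransformJson:
    def test_round_trip(self, rng):
        t = RigidTransform(random_rotation(rng), rng.normal(size=3))
        t2 = RigidTransform.from_json(t.to_json())
        np.testing.assert_allclose(t2.rotation, t.rotation)
        np.testing.assert_allclose(t2.translation, t.translation)
        rec = json.loads(t.to_json())
        assert set(rec) == {"rotation", "translation", "euler_convention"}
        assert len(rec["rotation"]) == 9

    def test_compose_and_inverse(self, rng):
        a = RigidTransform(random_rotation(rng), rng.normal(size=3))
        b = RigidTransform(random_rotation(rng), rng.normal(size=3))
        p = rng.normal(size=(5, 3))
        np.testing.assert_allclose(
            a.compose(b).apply_points(p), a.apply_points(b.apply_points(p)), atol=1e-9
        )
        np.testing.assert_allclose(a.inverse().apply_points(a.apply_points(p)), p, atol=1e-9)


def test_rotation_angle_of_known_rotation():
    R = rotation_from_euler([0.0, 0.0, 0.25])
    assert rotation_angle(R) == pytest.approx(0.25, abs=1e-12)
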