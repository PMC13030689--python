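"""Training objectives against independent brute-force oracles.

Every composite loss is re-derived in the tests by explicit element-wise
summation (double loops), and closed-form spot values (ln 2, the 3-4-5
triangle, 3*sqrt(3)) are asserted exactly.
"""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pelvimark.geometry import LANDMARK_NAMES, LandmarkSet, euler_from_rotation
from pelvimark.losses import (
    LossWeights,
    align_total_loss,
    euler_angle_loss,
    landmark_total_loss,
    marker_distance_loss,
    nll_loss,
    point_set_distance,
    rotation_regularization,
)


def random_log_probs(rng, n, c):
    z = rng.normal(size=(n, c))
    return z - np.log(np.exp(z).sum(axis=1, keepdims=True))


class TestNll:
    def test_uniform_two_class_is_ln2(self):
        lp = np.log(np.full((10, 2), 0.5))
        assert nll_loss(lp, np.zeros(10, dtype=int)) == pytest.approx(np.log(2.0), abs=1e-12)

    def test_perfect_one_hot_is_zero(self):
        lp = np.full((4, 3), -1e9)
        y = np.array([0, 1, 2, 1])
        lp[np.arange(4), y] = 0.0
        assert nll_loss(lp, y) == pytest.approx(0.0, abs=1e-12)

    def test_weighted_case_matches_hand_sum(self, rng):
        lp = random_log_probs(rng, 10, 3)
        y = rng.integers(0, 3, size=10)
        w = np.array([1.0, 2.0, 0.5])
        expect = -sum(w[y[i]] * lp[i, y[i]] for i in range(10)) / 10
        assert nll_loss(lp, y, w) == pytest.approx(expect, abs=1e-10)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            nll_loss(random_log_probs(rng, 5, 2), np.zeros(6, dtype=int))

    def test_label_out_of_range_raises(self, rng):
        with pytest.raises(ValueError):
            nll_loss(random_log_probs(rng, 5, 2), np.full(5, 3))


class TestPointSetDistance:
    def test_identical_clouds_give_zero(self, rng):
        p = rng.normal(size=(20, 3))
        assert point_set_distance(p, p) == 0.0

    def test_uniform_345_shift(self, rng):
        p = rng.normal(size=(20, 3))
        assert point_set_distance(p + [3.0, 4.0, 0.0], p) == pytest.approx(5.0, abs=1e-12)

    def test_matches_summation_oracle(self, rng):
        a, b = rng.normal(size=(2, 15, 3))
        expect = sum(np.sqrt(((a[i] - b[i]) ** 2).sum()) for i in range(15)) / 15
        assert point_set_distance(a, b) == pytest.approx(expect, abs=1e-10)

    def test_batched_matches_flat_mean(self, rng):
        a, b = rng.normal(size=(2, 4, 10, 3))
        per = [point_set_distance(a[i], b[i]) for i in range(4)]
        assert point_set_distance(a, b) == pytest.approx(np.mean(per), abs=1e-12)

    def test_count_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            point_set_distance(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))


class TestRotationRegularization:
    def test_identity_is_zero(self):
        assert rotation_regularization(np.eye(3)) == pytest.approx(0.0, abs=1e-12)

    def test_doubled_identity(self):
        assert rotation_regularization(2.0 * np.eye(3)) == pytest.approx(3 * np.sqrt(3), abs=1e-12)

    def test_zero_for_any_orthonormal_including_reflections(self, rng):
        R = Rotation.random(random_state=0).as_matrix()
        assert rotation_regularization(R) < 1e-12
        R[:, 0] *= -1.0  # det -1 reflection still satisfies R^T R = I
        assert rotation_regularization(R) < 1e-12

    def test_matches_frobenius_oracle(self, rng):
        M = rng.normal(size=(3, 3))
        res = np.eye(3) - M.T @ M
        expect = np.sqrt((res**2).sum())
        assert rotation_regularization(M) == pytest.approx(expect, abs=1e-10)


class TestEulerAngleLoss:
    def test_equal_rotations_give_zero(self):
        R = Rotation.random(random_state=1).as_matrix()
        assert euler_angle_loss(R, R) == pytest.approx(0.0, abs=1e-12)

    def test_z_rotation_against_identity(self):
        R = Rotation.from_euler("XYZ", [0, 0, 0.1]).as_matrix()
        assert euler_angle_loss(R, np.eye(3)) == pytest.approx(0.1, abs=1e-10)

    def test_matches_conversion_then_norm_oracle(self, rng):
        A = Rotation.from_euler("XYZ", rng.uniform(-1, 1, 3)).as_matrix()
        B = Rotation.from_euler("XYZ", rng.uniform(-1, 1, 3)).as_matrix()
        ta = euler_from_rotation(A).as_array()
        tb = euler_from_rotation(B).as_array()
        assert euler_angle_loss(A, B) == pytest.approx(np.linalg.norm(ta - tb), abs=1e-8)


class TestAlignTotal:
    def test_reduces_to_point_distance_when_weights_zero(self, rng):
        pred, ref = rng.normal(size=(2, 10, 3))
        R = rng.normal(size=(3, 3))
        w = LossWeights(lambda_rot=0.0, lambda_euler=0.0)
        total, parts = align_total_loss(pred, ref, R, np.eye(3), w)
        assert total == pytest.approx(point_set_distance(pred, ref), abs=1e-12)

    def test_perfect_prediction_is_zero(self, rng):
        p = rng.normal(size=(10, 3))
        R = Rotation.random(random_state=2).as_matrix()
        total, _ = align_total_loss(p, p, R, R)
        assert total == pytest.approx(0.0, abs=1e-9)

    def test_recombination_oracle(self, rng):
        pred, ref = rng.normal(size=(2, 10, 3))
        Rp = Rotation.random(random_state=3).as_matrix() + 0.1 * rng.normal(size=(3, 3))
        Rr = Rotation.random(random_state=4).as_matrix()
        w = LossWeights(lambda_rot=0.3, lambda_euler=2.0)
        from pelvimark.geometry import svd_project

        Rp_proj = svd_project(Rp)
        total, parts = align_total_loss(pred, ref, Rp_proj, Rr, w)
        expect = (
            point_set_distance(pred, ref)
            + 0.3 * rotation_regularization(Rp_proj)
            + 2.0 * euler_angle_loss(Rp_proj, Rr)
        )
        assert total == pytest.approx(expect, abs=1e-10)
        assert set(parts) == {"pts", "rot", "euler"}


class TestMarkerDistance:
    def test_perfect_centers_give_zero(self, canonical_landmarks):
        assert marker_distance_loss(canonical_landmarks, canonical_landmarks) == 0.0

    def test_single_offset_averaged_over_six(self, canonical_landmarks):
        pred = LandmarkSet(dict(canonical_landmarks))
        pred["L4"] = canonical_landmarks["L4"] + np.array([6.0, 0, 0])
        assert marker_distance_loss(pred, canonical_landmarks) == pytest.approx(1.0, abs=1e-12)

    def test_mean_of_three_offsets(self):
        gt = LandmarkSet(PSIS_L=(0, 0, 0), PSIS_R=(100, 0, 0), L4=(50, 70, 0))
        pred = LandmarkSet(
            PSIS_L=(1.0, 0, 0), PSIS_R=(100, 2.0, 0), L4=(50, 70, 3.0)
        )
        assert marker_distance_loss(pred, gt) == pytest.approx(2.0, abs=1e-12)

    def test_markers_absent_from_gt_excluded(self, canonical_landmarks):
        gt = LandmarkSet(L4=canonical_landmarks["L4"])
        pred = LandmarkSet(dict(canonical_landmarks))
        assert marker_distance_loss(pred, gt) == pytest.approx(0.0, abs=1e-12)

    def test_unpredicted_marker_contributes_penalty(self, canonical_landmarks):
        pred = LandmarkSet({n: v for n, v in canonical_landmarks.items() if n != "L1"})
        got = marker_distance_loss(pred, canonical_landmarks, missing_penalty_mm=50.0)
        assert got == pytest.approx(50.0 / 6.0, abs=1e-12)

    def test_empty_gt_raises(self, canonical_landmarks):
        with pytest.raises(ValueError):
            marker_distance_loss(canonical_landmarks, LandmarkSet())


class TestLandmarkTotal:
    def test_reduces_to_nll_when_lambda_zero(self, rng, canonical_landmarks):
        lp = random_log_probs(rng, 20, 7)
        y = rng.integers(0, 7, size=20)
        w = LossWeights(lambda_dist=0.0)
        total, _ = landmark_total_loss(lp, y, canonical_landmarks, canonical_landmarks, w)
        assert total == pytest.approx(nll_loss(lp, y), abs=1e-12)

    def test_default_lambda_is_ten(self):
        assert LossWeights().lambda_dist == 10.0

    def test_recombination_oracle(self, rng, canonical_landmarks):
        lp = random_log_probs(rng, 20, 7)
        y = rng.integers(0, 7, size=20)
        pred = LandmarkSet(
            {n: v + rng.normal(scale=2.0, size=3) for n, v in canonical_landmarks.items()}
        )
        total, parts = landmark_total_loss(lp, y, pred, canonical_landmarks)
        expect = nll_loss(lp, y) + 10.0 * marker_distance_loss(pred, canonical_landmarks)
        assert total == pytest.approx(expect, abs=1e-10)


class TestOracleSweep:
    """Each loss matches its naive double-loop oracle on 20 seeded instances."""

    @pytest.mark.parametrize("seed", range(20))
    def test_all_losses_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n, c = 12, 4
        lp = random_log_probs(rng, n, c)
        y = rng.integers(0, c, size=n)
        w = rng.uniform(0.5, 2.0, size=c)
        expect_nll = -np.mean([w[y[i]] * lp[i, y[i]] for i in range(n)])
        assert nll_loss(lp, y, w) == pytest.approx(expect_nll, abs=1e-10)

        a, b = rng.normal(size=(2, n, 3))
        expect_pts = np.mean([np.linalg.norm(a[i] - b[i]) for i in range(n)])
        assert point_set_distance(a, b) == pytest.approx(expect_pts, abs=1e-10)

        M = rng.normal(size=(3, 3))
        expect_rot = np.linalg.norm(np.eye(3) - M.T @ M, "fro")
        assert rotation_regularization(M) == pytest.approx(expect_rot, abs=1e-10)

        Ra = Rotation.random(random_state=seed).as_matrix()
        Rb = Rotation.random(random_state=seed + 1000).as_matrix()
        expect_euler = np.linalg.norm(
            euler_from_rotation(Ra).as_array() - euler_from_rotation(Rb).as_array()
        )
        assert euler_angle_loss(Ra, Rb) == pytest.approx(expect_euler, abs=1e-10)


class TestLossProperties:
    def test_losses_nonnegative(self, rng, canonical_landmarks):
        lp = random_log_probs(rng, 30, 7)
        y = rng.integers(0, 7, size=30)
        assert nll_loss(lp, y) >= 0.0
        assert point_set_distance(rng.normal(size=(5, 3)), rng.normal(size=(5, 3))) >= 0.0
        assert rotation_regularization(rng.normal(size=(3, 3))) >= 0.0
        assert marker_distance_loss(canonical_landmarks, canonical_landmarks) >= 0.0

    def test_gradient_check_on_training_losses(self, rng):
        """Autodiff gradients of the trainable loss expressions agree with
        central finite differences on small instances."""
        from pelvimark.nn import Tensor

        # weighted NLL through log-softmax
        z0 = rng.normal(size=(6, 3))
        y = rng.integers(0, 3, size=6)
        w = rng.uniform(0.5, 2.0, size=3)

        def nll_of(z):
            t = Tensor(z, requires_grad=True)
            lp = t.log_softmax(-1)
            picked = lp[(np.arange(6), y)]
            return t, -(picked * w[y]).mean()

        t, loss = nll_of(z0)
        loss.backward()
        g = t.grad
        eps = 1e-6
        for idx in [(0, 0), (2, 1), (5, 2)]:
            zp, zm = z0.copy(), z0.copy()
            zp[idx] += eps
            zm[idx] -= eps
            num = (nll_of(zp)[1].value - nll_of(zm)[1].value) / (2 * eps)
            assert g[idx] == pytest.approx(float(num), abs=1e-4)
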