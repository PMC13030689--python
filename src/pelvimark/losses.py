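"""Training objectives for the three pipeline stages.

Segmentation stages (ROI and landmark labeling) use a per-point negative
log-likelihood with optional class weighting.  The alignment stage combines
an index-paired point-set distance, an orthonormality regularizer on the
raw predicted matrix, and an l2 distance between Euler-angle representations.
The landmark stage adds a marker-center distance term weighted by
``lambda_dist`` (default 10).

All functions here are plain NumPy and are the reference definitions; the
training loops evaluate structurally identical expressions on autodiff
tensors (`pelvimark.nn`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import LANDMARK_NAMES, LandmarkSet, euler_from_rotation
from .preprocessing import LabelVector

__all__ = [
    "LossWeights",
    "nll_loss",
    "point_set_distance",
    "rotation_regularization",
    "euler_angle_loss",
    "align_total_loss",
    "marker_distance_loss",
    "landmark_total_loss",
]


@dataclass
class LossWeights:
    """Scalar weights of the composite objectives.

    ``class_weights`` — per-class weights of the NLL term (uniform default);
    ``lambda_rot`` / ``lambda_euler`` — alignment regularizer weights;
    ``lambda_dist`` — marker-center distance weight (default 10);
    ``missing_marker_penalty_mm`` — distance charged for a ground-truth
    marker with no prediction during training-time center losses.
    """

    class_weights: np.ndarray | None = None
    lambda_rot: float = 0.1
    lambda_euler: float = 1.0
    lambda_dist: float = 10.0
    missing_marker_penalty_mm: float = 50.0

    def __post_init__(self):
        if self.class_weights is not None:
            self.class_weights = np.asarray(self.class_weights, dtype=float)
            if (self.class_weights < 0).any():
                raise ValueError("class weights must be non-negative")
        for name in ("lambda_rot", "lambda_euler", "lambda_dist"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _labels_array(labels) -> np.ndarray:
    if isinstance(labels, LabelVector):
        return labels.labels
    return np.asarray(labels, dtype=np.int64).ravel()


def nll_loss(log_probs: np.ndarray, labels, class_weights: np.ndarray | None = None) -> float:
    """Weighted negative log-likelihood: -(1/N) sum_i w_{y_i} log p_{i,y_i}."""
    lp = np.asarray(log_probs, dtype=float)
    y = _labels_array(labels)
    if lp.ndim != 2 or lp.shape[0] != y.size:
        raise ValueError(f"log_probs {lp.shape} and labels {y.shape} mismatch")
    if y.size and (y.min() < 0 or y.max() >= lp.shape[1]):
        raise ValueError("labels out of range for the class dimension")
    w = np.ones(lp.shape[1]) if class_weights is None else np.asarray(class_weights, dtype=float)
    if w.shape != (lp.shape[1],):
        raise ValueError("class weight length must equal the class count")
    return float(-(w[y] * lp[np.arange(y.size), y]).mean())


def point_set_distance(pred: np.ndarray, ref: np.ndarray) -> float:
    """Mean index-paired Euclidean distance (mm) between two point sets.

    Accepts (N, 3) or batched (B, N, 3) arrays; points correspond by index —
    no nearest-neighbour matching is performed.
    """
    p = np.asarray(pred, dtype=float)
    r = np.asarray(ref, dtype=float)
    if p.shape != r.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {r.shape}")
    return float(np.linalg.norm(p - r, axis=-1).mean())


def rotation_regularization(R: np.ndarray) -> float:
    """Orthonormality residual ||I - R^T R||_F, averaged over any batch dim."""
    R = np.asarray(R, dtype=float)
    if R.ndim == 2:
        R = R[None]
    eye = np.eye(3)
    res = eye - np.einsum("bji,bjk->bik", R, R)
    return float(np.linalg.norm(res, axis=(1, 2)).mean())


def euler_angle_loss(R_pred: np.ndarray, R_ref: np.ndarray) -> float:
    """l2 distance (rad) between the Euler-angle vectors of two rotations."""
    Rp = np.asarray(R_pred, dtype=float)
    Rr = np.asarray(R_ref, dtype=float)
    if Rp.ndim == 2:
        Rp, Rr = Rp[None], Rr[None]
    vals = [
        np.linalg.norm(
            euler_from_rotation(a).as_array() - euler_from_rotation(b).as_array()
        )
        for a, b in zip(Rp, Rr)
    ]
    return float(np.mean(vals))


def align_total_loss(
    pred_cloud: np.ndarray,
    ref_cloud: np.ndarray,
    R_pred: np.ndarray,
    R_ref: np.ndarray,
    w: LossWeights | None = None,
) -> tuple[float, dict[str, float]]:
    """Alignment objective: L_pts + lambda_rot L_rot + lambda_euler L_euler."""
    w = w or LossWeights()
    parts = {
        "pts": point_set_distance(pred_cloud, ref_cloud),
        "rot": rotation_regularization(R_pred),
        # the Euler term requires orthonormal inputs; with zero weight it is
        # skipped so the loss stays defined for raw (unprojected) matrices
        "euler": euler_angle_loss(R_pred, R_ref) if w.lambda_euler != 0 else 0.0,
    }
    total = parts["pts"] + w.lambda_rot * parts["rot"] + w.lambda_euler * parts["euler"]
    return float(total), parts


def marker_distance_loss(
    pred: LandmarkSet,
    gt: LandmarkSet,
    missing_penalty_mm: float | None = 50.0,
) -> float:
    """Mean Euclidean distance (mm) between predicted and true marker centers.

    Averaged over the markers present in the ground truth; a ground-truth
    marker with no prediction contributes ``missing_penalty_mm`` (pass None
    to exclude unpredicted markers instead, as evaluation does).
    """
    names = [n for n in LANDMARK_NAMES if n in gt]
    if not names:
        raise ValueError("ground truth contains no markers")
    dists = []
    for n in names:
        if n in pred:
            dists.append(float(np.linalg.norm(pred[n] - gt[n])))
        elif missing_penalty_mm is not None:
            dists.append(float(missing_penalty_mm))
    if not dists:
        raise ValueError("no marker has both a prediction and a ground truth")
    return float(np.mean(dists))


def landmark_total_loss(
    log_probs: np.ndarray,
    labels,
    pred_centers: LandmarkSet,
    gt_centers: LandmarkSet,
    w: LossWeights | None = None,
) -> tuple[float, dict[str, float]]:
    """Landmark objective: L_NLL + lambda_dist L_dist."""
    w = w or LossWeights()
    parts = {
        "nll": nll_loss(log_probs, labels, w.class_weights),
        "dist": marker_distance_loss(
            pred_centers, gt_centers, missing_penalty_mm=w.missing_marker_penalty_mm
        ),
    }
    total = parts["nll"] + w.lambda_dist * parts["dist"]
    return float(total), parts
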