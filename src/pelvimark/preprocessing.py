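"""Point-cloud preprocessing: ROI boxes, region labels, sampling, augmentation.

The ROI of the posterior pelvis is the axis-aligned bounding box of the six
skin markers expanded by a fixed margin (100 mm by default) on every side.
For landmark-region labeling every point within a fixed radius (10 mm by
default) of a marker inherits that marker's class (1..6 in the canonical
order); everything else is background (0).  Both the inside-box and the
inside-radius tests are closed (<=) so boundary points count as inside.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import (
    LANDMARK_NAMES,
    LandmarkSet,
    PointCloud,
    RigidTransform,
    rotation_from_euler,
)

__all__ = [
    "ROIBox",
    "LabelVector",
    "AugmentationConfig",
    "AugmentedSample",
    "InsufficientPointsError",
    "roi_box_from_markers",
    "label_points_in_box",
    "label_landmark_regions",
    "downsample_uniform",
    "build_point_features",
    "augment",
    "simulate_manual_crop",
]


class InsufficientPointsError(ValueError):
    """A cloud has fewer points than an operation requires."""


@dataclass(frozen=True)
class ROIBox:
    """Axis-aligned box given by per-axis (min, max) bounds in mm."""

    bounds: np.ndarray  # 3 x 2

    def __post_init__(self):
        b = np.asarray(self.bounds, dtype=float).reshape(3, 2)
        if not (b[:, 0] < b[:, 1]).all():
            raise ValueError("box min must be strictly below max on every axis")
        object.__setattr__(self, "bounds", b)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Closed-interval membership test for an N x 3 array."""
        p = np.asarray(points, dtype=float)
        lo, hi = self.bounds[:, 0], self.bounds[:, 1]
        return np.all((p >= lo) & (p <= hi), axis=1)


@dataclass
class LabelVector:
    """Per-point integer class labels companion to a PointCloud."""

    labels: np.ndarray
    n_classes: int
    kind: str = "roi"  # "roi": {0 other, 1 pelvic}; "landmark": {0 bg, 1..6 markers}

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64).ravel()
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= self.n_classes):
            raise ValueError("labels out of range [0, n_classes)")

    def __len__(self) -> int:
        return self.labels.size

    def subset(self, index: np.ndarray) -> "LabelVector":
        return replace(self, labels=self.labels[index])


@dataclass
class AugmentationConfig:
    """Offline rigid augmentation: centroid translation + small random rotation.

    Each augmented sample is the cloud translated to its centroid and rotated
    by independent per-axis angles drawn uniformly from
    [-rotation_range_deg, +rotation_range_deg]; the applied rotation is
    recorded because it is the regression target of the alignment stage.
    """

    rotation_range_deg: float = 20.0
    factor: int = 20
    downsample_n: int = 16384
    seed: int = 0

    def __post_init__(self):
        if self.factor < 1:
            raise ValueError("factor must be >= 1")
        if self.downsample_n < 1:
            raise ValueError("downsample_n must be >= 1")
        if self.rotation_range_deg < 0:
            raise ValueError("rotation range must be >= 0")


@dataclass
class AugmentedSample:
    cloud: PointCloud
    labels: LabelVector | None
    landmarks: LandmarkSet | None
    rotation: np.ndarray        # applied rotation matrix
    centroid: np.ndarray        # centroid subtracted before rotating


def roi_box_from_markers(landmarks: LandmarkSet, margin_mm: float = 100.0) -> ROIBox:
    """Marker bounding box expanded by ``margin_mm`` on every side."""
    if len(landmarks) == 0:
        raise ValueError("landmark set is empty")
    pts = np.stack([landmarks[n] for n in landmarks])
    lo = pts.min(axis=0) - margin_mm
    hi = pts.max(axis=0) + margin_mm
    return ROIBox(np.stack([lo, hi], axis=1))


def label_points_in_box(cloud: PointCloud, box: ROIBox) -> LabelVector:
    """Binary labels: 1 inside the (closed) box, 0 outside."""
    return LabelVector(box.contains(cloud.positions).astype(np.int64), 2, kind="roi")


def label_landmark_regions(
    cloud: PointCloud, landmarks: LandmarkSet, radius_mm: float = 10.0
) -> LabelVector:
    """Assign class k (1..6) to points within ``radius_mm`` of marker k.

    A point inside more than one marker sphere takes the nearest marker's
    class; the boundary (distance exactly equal to the radius) is inside.
    """
    if len(landmarks) == 0:
        raise ValueError("landmark set is empty")
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    pos = cloud.positions
    dists = np.full((pos.shape[0], len(LANDMARK_NAMES)), np.inf)
    for k, name in enumerate(LANDMARK_NAMES):
        if name in landmarks:
            dists[:, k] = np.linalg.norm(pos - landmarks[name], axis=1)
    nearest = dists.argmin(axis=1)
    within = dists[np.arange(pos.shape[0]), nearest] <= radius_mm
    labels = np.where(within, nearest + 1, 0)
    return LabelVector(labels, len(LANDMARK_NAMES) + 1, kind="landmark")


def downsample_uniform(
    cloud: PointCloud,
    n: int = 16384,
    seed: int | np.random.Generator = 0,
    labels: LabelVector | None = None,
):
    """Random uniform subsample of exactly ``n`` points, without replacement.

    Returns the subsampled cloud, or a (cloud, labels) pair when a companion
    label vector is supplied.  Deterministic for a fixed seed.
    """
    if cloud.n_points < n:
        raise InsufficientPointsError(
            f"cloud has {cloud.n_points} points, fewer than the requested {n}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(cloud.n_points, size=n, replace=False)
    sub = cloud.subset(idx)
    if labels is None:
        return sub
    return sub, labels.subset(idx)


def build_point_features(cloud: PointCloud) -> PointCloud:
    """Attach the six per-point input channels used by every network stage.

    Channels 1-3 are the raw (x, y, z) in mm; channels 4-6 are the same
    coordinates min-max normalized to [0, 1] over the cloud's own axis-aligned
    bounding box.  An axis with zero extent normalizes to 0.5.
    """
    pos = cloud.positions
    lo = pos.min(axis=0)
    extent = pos.max(axis=0) - lo
    norm = np.empty_like(pos)
    for ax in range(3):
        if extent[ax] > 0:
            norm[:, ax] = (pos[:, ax] - lo[ax]) / extent[ax]
        else:
            norm[:, ax] = 0.5
    return replace(cloud, features=np.concatenate([pos, norm], axis=1))


def augment(
    cloud: PointCloud,
    labels: LabelVector | None,
    landmarks: LandmarkSet | None,
    cfg: AugmentationConfig,
) -> list[AugmentedSample]:
    """Generate ``cfg.factor`` rigidly perturbed copies of a sample.

    Per-sample child seeds are derived from the master seed by counter so a
    dataset is reproducible regardless of generation order.
    """
    centroid = cloud.positions.mean(axis=0)
    out: list[AugmentedSample] = []
    rad = np.deg2rad(cfg.rotation_range_deg)
    for j in range(cfg.factor):
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, j)))
        angles = rng.uniform(-rad, rad, size=3)
        R = rotation_from_euler(angles)
        t = RigidTransform(R, -R @ centroid)
        new_cloud = replace(cloud, positions=t.apply_points(cloud.positions))
        new_marks = landmarks.transform(t) if landmarks is not None else None
        out.append(
            AugmentedSample(
                cloud=new_cloud,
                labels=labels,
                landmarks=new_marks,
                rotation=R,
                centroid=centroid,
            )
        )
    return out


def simulate_manual_crop(
    cloud: PointCloud,
    landmarks: LandmarkSet,
    lo: float = 50.0,
    hi: float = 150.0,
    seed: int | np.random.Generator = 0,
    labels: LabelVector | None = None,
):
    """Emulate clinician-guided visual ROI cropping.

    The marker bounding box is expanded by six independent offsets drawn
    uniformly from [lo, hi] mm — one per lower and upper bound per axis —
    instead of the fixed margin; points outside the box are dropped.
    Returns the cropped cloud (with subset labels when supplied).
    """
    if len(landmarks) == 0:
        raise ValueError("landmark set is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    offsets = rng.uniform(lo, hi, size=(3, 2))
    pts = np.stack([landmarks[n] for n in landmarks])
    bounds = np.stack(
        [pts.min(axis=0) - offsets[:, 0], pts.max(axis=0) + offsets[:, 1]], axis=1
    )
    box = ROIBox(bounds)
    keep = box.contains(cloud.positions)
    if labels is None:
        return cloud.subset(keep)
    return cloud.subset(keep), labels.subset(keep)
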