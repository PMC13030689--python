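"""Sequential three-stage inference: ROI -> alignment -> landmarks.

`run_pipeline` composes the trained stages on a raw scan: downsample, ROI
segmentation, crop to the predicted pelvic points (mask, not a refitted
box), rotation correction about the crop centroid, landmark-region
labeling, hard-label center extraction, and finally the inverse correction
so reported landmark coordinates live in the original scan frame.

At inference there is no ground truth, so only the predicted rotation is
applied; the canonical reference cloud of the training objective exists
only during training.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import LANDMARK_NAMES, LandmarkSet, PointCloud, RigidTransform
from .models import landmark_head, predict_rotation, segment_points
from .preprocessing import (
    build_point_features,
    downsample_uniform,
    simulate_manual_crop,
)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "RoiFailureError",
    "extract_marker_centers",
    "run_pipeline",
    "run_configuration",
    "ABLATION_ARMS",
]

ABLATION_ARMS = ("baseline", "crop+lm", "crop+align+lm", "roi+lm", "full")


class RoiFailureError(RuntimeError):
    """ROI stage kept too few points; carries the diagnostic mask."""

    def __init__(self, msg: str, mask: np.ndarray):
        super().__init__(msg)
        self.mask = mask


@dataclass
class PipelineConfig:
    scan_points: int = 4096       # raw-scan downsample count (ROI stage input)
    roi_points: int = 2048        # cap on points entering the landmark stage
    align_points: int = 1024      # cap on points entering the alignment stage
    baseline_points: int = 2048   # raw-scan downsample count of the baseline arm
    min_roi_points: int = 128     # below this the ROI stage is declared failed
    cluster_mm: float = 20.0      # dominant-cluster link distance for center extraction
    seed: int = 0


@dataclass
class PipelineResult:
    landmarks: LandmarkSet                 # original scan frame
    landmarks_aligned: LandmarkSet         # rotation-corrected frame
    roi_mask: np.ndarray                   # over the downsampled scan points
    correction: RigidTransform             # scan frame -> aligned frame
    timings_s: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)


def _largest_cluster(points: np.ndarray, link_mm: float) -> np.ndarray:
    """Indices of the largest single-linkage cluster at the given distance."""
    from scipy.spatial import cKDTree

    n = points.shape[0]
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in cKDTree(points).query_pairs(link_mm):
        parent[find(i)] = find(j)
    roots = np.array([find(i) for i in range(n)])
    counts = np.bincount(roots)
    return np.flatnonzero(roots == counts.argmax())


def extract_marker_centers(
    log_probs: np.ndarray, cloud: PointCloud, cluster_mm: float | None = None
) -> LandmarkSet:
    """Centroid of the points argmax-assigned to each landmark class.

    A class with no assigned point yields a missing marker.  With
    ``cluster_mm`` set, each class's points are first reduced to their
    largest single-linkage spatial cluster at that distance, so isolated
    stray points far from the predicted region do not drag the centroid
    (the pipeline uses this with twice the labeling radius).
    """
    lp = np.asarray(log_probs, dtype=float)
    if lp.ndim != 2 or lp.shape[1] != 7:
        raise ValueError(f"expected N x 7 log-probabilities, got {lp.shape}")
    if lp.shape[0] != cloud.n_points:
        raise ValueError("log-probabilities not row-aligned with the cloud")
    hard = lp.argmax(axis=1)
    out = LandmarkSet()
    for k, name in enumerate(LANDMARK_NAMES, start=1):
        sel = np.flatnonzero(hard == k)
        if sel.size == 0:
            continue
        pts = cloud.positions[sel]
        if cluster_mm is not None and sel.size > 1:
            pts = pts[_largest_cluster(pts, cluster_mm)]
        out[name] = pts.mean(axis=0)
    return out


def run_pipeline(
    raw_cloud: PointCloud,
    roinet,
    alignnet,
    landmarknet,
    cfg: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full three-stage pipeline on one raw scan."""
    cfg = cfg or PipelineConfig()
    timings: dict[str, float] = {}

    t0 = time.time()
    scan = downsample_uniform(raw_cloud, min(cfg.scan_points, raw_cloud.n_points), seed=cfg.seed)
    scan = build_point_features(scan)
    timings["downsample"] = time.time() - t0

    t0 = time.time()
    lp_roi = segment_points(roinet, scan, sampling_seed=cfg.seed)
    mask = lp_roi.argmax(axis=1) == 1
    timings["roi"] = time.time() - t0
    if mask.sum() < cfg.min_roi_points:
        raise RoiFailureError(
            f"ROI stage kept {int(mask.sum())} points (< {cfg.min_roi_points})", mask
        )
    roi_cloud = scan.subset(mask)
    if roi_cloud.n_points > cfg.roi_points:
        roi_cloud = downsample_uniform(roi_cloud, cfg.roi_points, seed=cfg.seed + 1)

    t0 = time.time()
    align_cloud = roi_cloud
    if align_cloud.n_points > cfg.align_points:
        align_cloud = downsample_uniform(align_cloud, cfg.align_points, seed=cfg.seed + 2)
    centroid = align_cloud.positions.mean(axis=0)
    centered = PointCloud(align_cloud.positions - centroid)
    R = predict_rotation(alignnet, build_point_features(centered), sampling_seed=cfg.seed)
    correction = RigidTransform(R, -R @ centroid)
    aligned = PointCloud(correction.apply_points(roi_cloud.positions))
    timings["align"] = time.time() - t0

    t0 = time.time()
    lp_lm = landmark_head(landmarknet, build_point_features(aligned), sampling_seed=cfg.seed)
    lm_aligned = extract_marker_centers(lp_lm, aligned, cluster_mm=cfg.cluster_mm)
    lm_scan = lm_aligned.transform(correction.inverse())
    timings["landmark"] = time.time() - t0

    return PipelineResult(
        landmarks=lm_scan,
        landmarks_aligned=lm_aligned,
        roi_mask=mask,
        correction=correction,
        timings_s=timings,
        provenance={
            "roinet": roinet.config.config_hash(),
            "alignnet": alignnet.config.config_hash(),
            "landmarknet": landmarknet.config.config_hash(),
            "seed": str(cfg.seed),
        },
    )


# ---------------------------------------------------------------------------
# ablation harness


@dataclass
class PipelineModels:
    roinet: object
    alignnet: object
    landmarknet: object
    baseline_lm: object | None = None  # landmark net trained on raw scans


def _errors_row(scan_id, subject_id, arm, pred: LandmarkSet, gt: LandmarkSet):
    rows = []
    for name in LANDMARK_NAMES:
        if name not in gt:
            continue
        err = float(np.linalg.norm(pred[name] - gt[name])) if name in pred else np.nan
        rows.append((arm, scan_id, subject_id, name, err))
    return rows


def run_configuration(
    name: str,
    records,
    models: PipelineModels,
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-scan, per-landmark errors (mm) for one ablation arm.

    Arms: ``baseline`` (landmark net on the raw downsampled scan),
    ``crop+lm`` (randomized manual crop, landmark net), ``crop+align+lm``,
    ``roi+lm`` (learned ROI, no alignment), ``full`` (the whole pipeline).
    Missing predictions are recorded as NaN, never dropped.
    """
    if name not in ABLATION_ARMS:
        raise ValueError(f"unknown arm {name!r}; expected one of {ABLATION_ARMS}")
    cfg = cfg or PipelineConfig()
    rows = []
    for i, rec in enumerate(records):
        scan_id = rec.cloud.scan_id or str(i)
        gt = rec.landmarks
        if name == "baseline":
            net = models.baseline_lm or models.landmarknet
            scan = downsample_uniform(
                rec.cloud, min(cfg.baseline_points, rec.cloud.n_points), seed=cfg.seed
            )
            lp = landmark_head(net, build_point_features(scan), sampling_seed=cfg.seed)
            pred = extract_marker_centers(lp, scan, cluster_mm=cfg.cluster_mm)
        elif name in ("crop+lm", "crop+align+lm"):
            crop = simulate_manual_crop(rec.cloud, gt, seed=cfg.seed + i)
            if crop.n_points > cfg.roi_points:
                crop = downsample_uniform(crop, cfg.roi_points, seed=cfg.seed)
            if name == "crop+align+lm":
                acloud = crop
                if acloud.n_points > cfg.align_points:
                    acloud = downsample_uniform(acloud, cfg.align_points, seed=cfg.seed + 2)
                centroid = acloud.positions.mean(axis=0)
                centered = PointCloud(acloud.positions - centroid)
                R = predict_rotation(
                    models.alignnet, build_point_features(centered), sampling_seed=cfg.seed
                )
                corr = RigidTransform(R, -R @ centroid)
                aligned = PointCloud(corr.apply_points(crop.positions))
                lp = landmark_head(
                    models.landmarknet, build_point_features(aligned), sampling_seed=cfg.seed
                )
                pred = extract_marker_centers(lp, aligned, cluster_mm=cfg.cluster_mm).transform(corr.inverse())
            else:
                lp = landmark_head(
                    models.landmarknet, build_point_features(crop), sampling_seed=cfg.seed
                )
                pred = extract_marker_centers(lp, crop, cluster_mm=cfg.cluster_mm)
        elif name == "roi+lm":
            scan = downsample_uniform(
                rec.cloud, min(cfg.scan_points, rec.cloud.n_points), seed=cfg.seed
            )
            scan = build_point_features(scan)
            lp_roi = segment_points(models.roinet, scan, sampling_seed=cfg.seed)
            mask = lp_roi.argmax(axis=1) == 1
            if mask.sum() < cfg.min_roi_points:
                pred = LandmarkSet()
            else:
                roi_cloud = scan.subset(mask)
                if roi_cloud.n_points > cfg.roi_points:
                    roi_cloud = downsample_uniform(roi_cloud, cfg.roi_points, seed=cfg.seed + 1)
                lp = landmark_head(
                    models.landmarknet, build_point_features(roi_cloud), sampling_seed=cfg.seed
                )
                pred = extract_marker_centers(lp, roi_cloud, cluster_mm=cfg.cluster_mm)
        else:  # full
            try:
                pred = run_pipeline(
                    rec.cloud, models.roinet, models.alignnet, models.landmarknet, cfg
                ).landmarks
            except RoiFailureError:
                pred = LandmarkSet()
        rows.extend(_errors_row(scan_id, rec.subject_id, name, pred, gt))
    return pd.DataFrame(
        rows, columns=["arm", "scan_id", "subject_id", "landmark", "error_mm"]
    )
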