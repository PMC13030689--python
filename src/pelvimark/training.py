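"""Training loops for the three pipeline stages, plus dataset preparation.

Each stage trains on samples prepared from (synthetic or user) scans:

* ROI stage — raw scans downsampled to a fixed count, binary labels from
  the marker box with its 100 mm margin;
* alignment stage — ground-truth ROI crops brought to the canonical pose,
  then rigidly augmented; the recorded rotation is the regression target and
  the canonical cloud (centroid-translated) is the index-paired reference;
* landmark stage — canonical ROI crops with 10 mm-radius region labels and
  the ground-truth marker centers for the distance term.

Sampling/grouping hierarchies depend only on point coordinates, so they are
built once per sample and cached across epochs.  Splits are always at the
subject level: all scans of a subject fall on one side.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import (
    LANDMARK_NAMES,
    LandmarkSet,
    PointCloud,
    RigidTransform,
    canonicalize_pose,
    euler_from_rotation,
    rotation_angle,
)
from .losses import LossWeights
from .nn import Adam, PointHierarchy, Tensor, atan2, concat, maximum_scalar, stack, stack_hierarchies
from .nn.pointnet2 import AlignmentNet, SegmentationNet
from .models import build_alignnet, build_landmarknet, build_roinet
from .preprocessing import (
    AugmentationConfig,
    augment,
    build_point_features,
    downsample_uniform,
    label_landmark_regions,
    label_points_in_box,
    roi_box_from_markers,
)
from .synthetic import ScanRecord

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "split_subjects",
    "prepare_roi_samples",
    "prepare_align_samples",
    "prepare_landmark_samples",
    "train_roinet",
    "train_alignnet",
    "train_landmarknet",
    "evaluate_roi",
    "evaluate_alignment",
    "evaluate_landmarks",
    "inverse_frequency_weights",
]


@dataclass
class TrainConfig:
    """Stage-agnostic training configuration."""

    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    split_ratio: float = 0.8          # train fraction at the subject level
    val_ratio: float = 0.2            # validation subjects carved from training data
    preset: str = "tiny"              # model preset: "tiny" | "full"
    scan_points: int = 2048           # raw-scan downsample count (ROI stage)
    roi_points: int = 2048            # ROI-crop downsample count (landmark stage)
    align_points: int = 512           # ROI-crop downsample count (alignment stage)
    final_lr_fraction: float = 1.0    # exponential LR decay target (1 = constant)
    dist_warmup_fraction: float = 0.5  # epochs fraction before the center-distance term engages
    pipeline_scan_points: int = 4096  # scan downsample count when cropping with a trained ROI net
    roi_margin_mm: float = 100.0
    label_radius_mm: float = 10.0
    augment_factor: int = 4
    augment_range_deg: float = 20.0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 < self.split_ratio < 1:
            raise ValueError("split ratio must lie in (0, 1)")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    components: list[dict[str, float]] = field(default_factory=list)
    best_epoch: int = -1
    wall_time_s: float = 0.0


def split_subjects(dataset: list, ratio: float = 0.8, seed: int = 0):
    """Subject-disjoint split of any items carrying ``subject_id``."""
    subjects = sorted({rec.subject_id for rec in dataset})
    if len(subjects) < 2:
        raise ValueError("need at least two subjects to split")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(subjects))
    n_train = int(round(ratio * len(subjects)))
    n_train = min(max(n_train, 1), len(subjects) - 1)
    train_set = set(order[:n_train])
    train = [r for r in dataset if r.subject_id in train_set]
    test = [r for r in dataset if r.subject_id not in train_set]
    return train, test


# ---------------------------------------------------------------------------
# sample preparation


@dataclass
class SegSample:
    xyz: np.ndarray
    feats: np.ndarray
    labels: np.ndarray
    subject_id: str
    scan_id: str


@dataclass
class AlignSample:
    xyz: np.ndarray        # network input: centroid-translated, rotated cloud
    feats: np.ndarray
    R_target: np.ndarray   # correction rotation (undoes the applied rotation)
    ref: np.ndarray        # index-paired reference points (canonical - centroid)
    subject_id: str


@dataclass
class LmSample:
    xyz: np.ndarray
    feats: np.ndarray
    labels: np.ndarray
    gt_centers: np.ndarray   # (6, 3)
    present: np.ndarray      # (6,) bool
    subject_id: str
    scan_id: str


def _canonical_roi_crop(
    rec: ScanRecord,
    cfg: TrainConfig,
    seed,
    n_points: int | None = None,
    roinet=None,
    cache: dict | None = None,
):
    """ROI crop, downsampled and brought to the canonical pose.

    With ``roinet`` supplied the crop is the network's predicted pelvic mask
    on the pipeline-scale downsampled scan — the same ragged point subsets
    the trained stage will see at inference; otherwise (or when the mask is
    too small) the ground-truth marker box is used.  ``cache`` memoizes the
    predicted masks per scan so several stages can share them.
    """
    crop = None
    if roinet is not None:
        key = id(rec)
        if cache is not None and key in cache:
            crop = cache[key]
        else:
            from .models import segment_points

            import zlib

            scan = rec.cloud
            if scan.n_points > cfg.pipeline_scan_points:
                tag = zlib.crc32((rec.cloud.scan_id or "scan").encode())
                scan = downsample_uniform(
                    scan, cfg.pipeline_scan_points,
                    seed=np.random.default_rng((cfg.seed, 77, tag)),
                )
            scan = build_point_features(scan)
            mask = segment_points(roinet, scan, sampling_seed=cfg.seed).argmax(axis=1) == 1
            crop = scan.subset(mask) if mask.sum() >= 256 else None
            if cache is not None:
                cache[key] = crop
    if crop is None:
        box = roi_box_from_markers(rec.landmarks, cfg.roi_margin_mm)
        crop = rec.cloud.subset(box.contains(rec.cloud.positions))
    n = min(n_points or cfg.roi_points, crop.n_points)
    crop = downsample_uniform(crop, n, seed=seed)
    t = canonicalize_pose(rec.landmarks)
    pts = t.apply_points(crop.positions)
    lms = rec.landmarks.transform(t)
    return replace(crop, positions=pts, features=None), lms


def prepare_roi_samples(records: list[ScanRecord], cfg: TrainConfig) -> list[SegSample]:
    out = []
    for i, rec in enumerate(records):
        box = roi_box_from_markers(rec.landmarks, cfg.roi_margin_mm)
        labels = label_points_in_box(rec.cloud, box)
        cloud, labels = downsample_uniform(
            rec.cloud, cfg.scan_points, seed=np.random.default_rng((cfg.seed, 11, i)), labels=labels
        )
        cloud = build_point_features(cloud)
        out.append(SegSample(cloud.positions, cloud.features, labels.labels, rec.subject_id, rec.cloud.scan_id or str(i)))
    return out


def prepare_align_samples(
    records: list[ScanRecord], cfg: TrainConfig, roinet=None, crop_cache: dict | None = None
) -> list[AlignSample]:
    out = []
    for i, rec in enumerate(records):
        crop, _ = _canonical_roi_crop(
            rec, cfg, seed=np.random.default_rng((cfg.seed, 12, i)),
            n_points=cfg.align_points, roinet=roinet, cache=crop_cache,
        )
        aug_cfg = AugmentationConfig(
            rotation_range_deg=cfg.augment_range_deg,
            factor=cfg.augment_factor,
            seed=int(np.random.default_rng((cfg.seed, 13, i)).integers(2**31)),
        )
        for s in augment(crop, None, None, aug_cfg):
            cloud = build_point_features(s.cloud)
            out.append(
                AlignSample(
                    xyz=cloud.positions,
                    feats=cloud.features,
                    R_target=s.rotation.T,
                    ref=crop.positions - s.centroid,
                    subject_id=rec.subject_id,
                )
            )
    return out


def prepare_landmark_samples(
    records: list[ScanRecord],
    cfg: TrainConfig,
    mode: str = "canonical",
    radius_mm: float | None = None,
    roinet=None,
    crop_cache: dict | None = None,
) -> list[LmSample]:
    """Landmark-stage samples; ``mode='raw'`` uses raw downsampled scans
    (the baseline ablation arm), ``mode='canonical'`` the canonical ROI crops
    (predicted by ``roinet`` when given, ground-truth boxes otherwise)."""
    radius = cfg.label_radius_mm if radius_mm is None else radius_mm
    out = []
    for i, rec in enumerate(records):
        if mode == "raw":
            cloud = downsample_uniform(
                rec.cloud, cfg.scan_points, seed=np.random.default_rng((cfg.seed, 14, i))
            )
            pairs = [(cloud, rec.landmarks)]
        else:
            crop, lms = _canonical_roi_crop(
                rec, cfg, seed=np.random.default_rng((cfg.seed, 14, i)),
                roinet=roinet, cache=crop_cache,
            )
            # keep the unrotated canonical sample alongside the rotated
            # copies: the stage's inference inputs are rotation-corrected,
            # i.e. near-canonical, and per-axis +-20 deg draws almost never
            # land there
            centroid = crop.positions.mean(axis=0)
            centered = replace(crop, positions=crop.positions - centroid)
            centered_lms = LandmarkSet({n: v - centroid for n, v in lms.items()})
            pairs = [(centered, centered_lms)]
            if cfg.augment_factor > 1:
                aug_cfg = AugmentationConfig(
                    rotation_range_deg=cfg.augment_range_deg,
                    factor=cfg.augment_factor - 1,
                    seed=int(np.random.default_rng((cfg.seed, 15, i)).integers(2**31)),
                )
                pairs += [(s.cloud, s.landmarks) for s in augment(crop, None, lms, aug_cfg)]
        for cloud, lms in pairs:
            labels = label_landmark_regions(cloud, lms, radius)
            cloud = build_point_features(cloud)
            centers = np.zeros((6, 3))
            present = np.zeros(6, dtype=bool)
            for k, name in enumerate(LANDMARK_NAMES):
                if name in lms:
                    centers[k] = lms[name]
                    present[k] = True
            out.append(
                LmSample(
                    cloud.positions, cloud.features, labels.labels,
                    centers, present, rec.subject_id, rec.cloud.scan_id or str(i),
                )
            )
    return out


def inverse_frequency_weights(
    samples: list, n_classes: int, cap: float = 10.0, power: float = 0.5
) -> np.ndarray:
    """Class weights from relative label frequencies, anchored at class 0.

    ``w_c = min(cap, (f_0 / f_c) ** power)`` with ``f_c`` the empirical
    frequency of class c, so the (majority) background class keeps weight 1
    and rare landmark classes are boosted but never dominate the objective.
    """
    counts = np.zeros(n_classes)
    for s in samples:
        counts += np.bincount(s.labels, minlength=n_classes)
    f = np.maximum(counts, 1.0) / counts.sum()
    return np.minimum(cap, (f[0] / f) ** power)


# ---------------------------------------------------------------------------
# generic training machinery


class _BatchedData:
    """Precomputes per-sample hierarchies and serves stacked mini-batches."""

    def __init__(self, samples, stages, seed: int, with_fp: bool):
        self.samples = samples
        self.hierarchies = [
            PointHierarchy(s.xyz, stages, seed=seed + 7 * i, with_fp=with_fp)
            for i, s in enumerate(samples)
        ]

    def batch(self, idx: np.ndarray):
        samples = [self.samples[i] for i in idx]
        h = stack_hierarchies([self.hierarchies[i] for i in idx])
        feats = np.stack([s.feats for s in samples])
        return samples, feats, h


def _val_split(samples, cfg: TrainConfig):
    subjects = sorted({s.subject_id for s in samples})
    if len(subjects) < 2:
        return samples, []
    rng = np.random.default_rng((cfg.seed, 99))
    order = list(rng.permutation(subjects))
    n_val = max(1, int(round(cfg.val_ratio * len(subjects))))
    val_set = set(order[:n_val])
    tr = [s for s in samples if s.subject_id not in val_set]
    va = [s for s in samples if s.subject_id in val_set]
    return tr, va


def _run_training(model, data_tr, data_va, cfg: TrainConfig, loss_fn, epoch_hook=None):
    t0 = time.time()
    params = model.parameters()
    opt = Adam(params, lr=cfg.learning_rate)
    rng = np.random.default_rng((cfg.seed, 42))
    hist = TrainHistory()
    best_val = np.inf
    best_state = [a.copy() for a in model.state_arrays()]
    n = len(data_tr.samples)
    for epoch in range(cfg.epochs):
        if cfg.final_lr_fraction < 1.0 and cfg.epochs > 1:
            opt.lr = cfg.learning_rate * cfg.final_lr_fraction ** (epoch / (cfg.epochs - 1))
        if epoch_hook is not None:
            epoch_hook(epoch)
        model.set_training(True)
        order = rng.permutation(n)
        epoch_losses, epoch_parts = [], []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            samples, feats, h = data_tr.batch(idx)
            loss, parts = loss_fn(model, samples, feats, h)
            if not np.isfinite(loss.value):
                raise FloatingPointError("non-finite training loss")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.value))
            epoch_parts.append(parts)
        hist.train_loss.append(float(np.mean(epoch_losses)))
        hist.components.append(
            {k: float(np.mean([p[k] for p in epoch_parts])) for k in epoch_parts[0]}
        )
        # validation
        model.set_training(False)
        if data_va.samples:
            v_losses = []
            m = len(data_va.samples)
            for start in range(0, m, cfg.batch_size):
                idx = np.arange(start, min(start + cfg.batch_size, m))
                samples, feats, h = data_va.batch(idx)
                loss, _ = loss_fn(model, samples, feats, h)
                v_losses.append(float(loss.value))
            val = float(np.mean(v_losses))
        else:
            val = hist.train_loss[-1]
        hist.val_loss.append(val)
        if val < best_val:
            best_val = val
            best_state = [a.copy() for a in model.state_arrays()]
            hist.best_epoch = epoch
    model.load_state_arrays(best_state)
    model.set_training(False)
    hist.wall_time_s = time.time() - t0
    return model, hist


def _seg_nll(log_probs: Tensor, samples, class_weights: np.ndarray) -> Tensor:
    y = np.stack([s.labels for s in samples])  # (B, N)
    B, N = y.shape
    bidx, nidx = np.meshgrid(np.arange(B), np.arange(N), indexing="ij")
    picked = log_probs[(bidx, nidx, y)]        # (B, N)
    return -(picked * class_weights[y]).mean()


# ---------------------------------------------------------------------------
# stage trainers


def train_roinet(
    data,
    cfg: TrainConfig,
    w: LossWeights | None = None,
    model: SegmentationNet | None = None,
):
    """Train the binary ROI segmentation stage; returns (model, history)."""
    if data and isinstance(data[0], ScanRecord):
        data = prepare_roi_samples(data, cfg)
    model = model or build_roinet(cfg.preset, seed=cfg.seed)
    tr, va = _val_split(data, cfg)
    d_tr = _BatchedData(tr, model.config.stages, cfg.seed, with_fp=True)
    d_va = _BatchedData(va, model.config.stages, cfg.seed + 1, with_fp=True)
    w = (w.class_weights if w and w.class_weights is not None else np.ones(2))

    def loss_fn(model, samples, feats, h):
        lp = model.forward(feats, h)
        loss = _seg_nll(lp, samples, w)
        return loss, {"nll": float(loss.value)}

    return _run_training(model, d_tr, d_va, cfg, loss_fn)


def _euler_tensor(R: Tensor) -> Tensor:
    """Intrinsic x->y->z Euler angles of a (B, 3, 3) rotation tensor."""
    B = R.value.shape[0]
    b = np.arange(B)
    ty = R[(b, 0, 2)].clip(-1.0 + 1e-9, 1.0 - 1e-9).arcsin()
    tx = atan2(-R[(b, 1, 2)], R[(b, 2, 2)])
    tz = atan2(-R[(b, 0, 1)], R[(b, 0, 0)])
    return stack([tx, ty, tz], axis=1)  # (B, 3)


def train_alignnet(
    data,
    cfg: TrainConfig,
    w: LossWeights | None = None,
    model: AlignmentNet | None = None,
    roinet=None,
):
    """Train the rotation-correction stage; returns (model, history)."""
    if data and isinstance(data[0], ScanRecord):
        data = prepare_align_samples(data, cfg, roinet=roinet)
    w = w or LossWeights()
    model = model or build_alignnet(cfg.preset, seed=cfg.seed)
    tr, va = _val_split(data, cfg)
    d_tr = _BatchedData(tr, model.config.stages, cfg.seed, with_fp=False)
    d_va = _BatchedData(va, model.config.stages, cfg.seed + 1, with_fp=False)
    eye = np.eye(3)

    def loss_fn(model, samples, feats, h):
        M, R = model.forward(feats, h)
        xyz = np.stack([s.xyz for s in samples])       # (B, N, 3)
        ref = np.stack([s.ref for s in samples])
        pred = Tensor(xyz) @ R.transpose(0, 2, 1)      # R p, row-vector form
        l_pts = (((pred - ref) ** 2).sum(axis=-1) + 1e-12).sqrt().mean()
        res = eye - M.transpose(0, 2, 1) @ M
        l_rot = ((res**2).sum(axis=(1, 2)) + 1e-12).sqrt().mean()
        theta_ref = np.stack(
            [euler_from_rotation(s.R_target).as_array() for s in samples]
        )
        diff = _euler_tensor(R) - theta_ref
        l_euler = ((diff**2).sum(axis=1) + 1e-12).sqrt().mean()
        total = l_pts + w.lambda_rot * l_rot + w.lambda_euler * l_euler
        return total, {
            "pts": float(l_pts.value),
            "rot": float(l_rot.value),
            "euler": float(l_euler.value),
        }

    return _run_training(model, d_tr, d_va, cfg, loss_fn)


def _soft_centers(log_probs: Tensor, xyz: np.ndarray, gate_fraction: float = 0.3) -> Tensor:
    """Probability-weighted marker centers, one per landmark class: (B, 6, 3).

    Differentiable stand-in for the hard-label centroids used at evaluation.
    Weights are the class probabilities restricted to the points whose
    probability is within ``gate_fraction`` of the per-cloud maximum (the
    gate itself is treated as a constant), so the center tracks the
    predicted blob rather than diffuse probability mass far away, and its
    gradient moves the blob instead of smearing probabilities globally.
    """
    probs = log_probs.exp()  # (B, N, 7)
    centers = []
    for k in range(1, 7):
        wk = probs[(slice(None), slice(None), k)]          # (B, N)
        gate = (
            wk.value >= gate_fraction * wk.value.max(axis=1, keepdims=True)
        ).astype(float)
        wk = wk * gate
        denom = maximum_scalar(wk.sum(axis=1), 1e-8)       # (B,)
        ck = (wk.reshape(wk.value.shape[0], -1, 1) * xyz).sum(axis=1) / denom.reshape(-1, 1)
        centers.append(ck)
    return stack(centers, axis=1)


def train_landmarknet(
    data,
    cfg: TrainConfig,
    w: LossWeights | None = None,
    model: SegmentationNet | None = None,
    mode: str = "canonical",
    roinet=None,
):
    """Train the landmark-region stage; returns (model, history)."""
    if data and isinstance(data[0], ScanRecord):
        data = prepare_landmark_samples(data, cfg, mode=mode, roinet=roinet)
    w = w or LossWeights()
    model = model or build_landmarknet(cfg.preset, seed=cfg.seed)
    class_w = (
        w.class_weights
        if w.class_weights is not None
        else inverse_frequency_weights(data, 7)
    )
    tr, va = _val_split(data, cfg)
    d_tr = _BatchedData(tr, model.config.stages, cfg.seed, with_fp=True)
    d_va = _BatchedData(va, model.config.stages, cfg.seed + 1, with_fp=True)
    # the center-distance term only engages once the label blobs have begun
    # to localize; before that the soft centers sit near the cloud centroid
    # and the term pushes probability mass in unhelpful directions
    state = {"lambda_dist": 0.0 if cfg.dist_warmup_fraction > 0 else w.lambda_dist}

    def epoch_hook(epoch):
        if epoch >= cfg.dist_warmup_fraction * cfg.epochs:
            state["lambda_dist"] = w.lambda_dist

    def loss_fn(model, samples, feats, h):
        lp = model.forward(feats, h)
        l_nll = _seg_nll(lp, samples, class_w)
        xyz = np.stack([s.xyz for s in samples])
        centers = _soft_centers(lp, xyz)                   # (B, 6, 3)
        gt = np.stack([s.gt_centers for s in samples])
        present = np.stack([s.present for s in samples]).astype(float)
        d = (((centers - gt) ** 2).sum(axis=-1) + 1e-12).sqrt()  # (B, 6)
        l_dist = (d * present).sum() / max(present.sum(), 1.0)
        # validation always scores the full objective so model selection is
        # consistent across the warmup boundary
        lam = state["lambda_dist"] if model.training else w.lambda_dist
        total = l_nll + lam * l_dist
        return total, {"nll": float(l_nll.value), "dist": float(l_dist.value)}

    return _run_training(model, d_tr, d_va, cfg, loss_fn, epoch_hook=epoch_hook)


# ---------------------------------------------------------------------------
# held-out evaluation helpers


def _eval_forward(model, samples, cfg: TrainConfig, with_fp: bool):
    model.set_training(False)
    data = _BatchedData(samples, model.config.stages, cfg.seed + 1000, with_fp=with_fp)
    outs = []
    for start in range(0, len(samples), cfg.batch_size):
        idx = np.arange(start, min(start + cfg.batch_size, len(samples)))
        _, feats, h = data.batch(idx)
        outs.append(model.forward(feats, h))
    return outs


def evaluate_roi(model, samples: list[SegSample], cfg: TrainConfig):
    """Pooled per-class IoU/recall of the ROI stage over held-out samples."""
    from .evaluation import iou_recall

    preds, gts = [], []
    for out, start in zip(
        _eval_forward(model, samples, cfg, with_fp=True),
        range(0, len(samples), cfg.batch_size),
    ):
        lp = out.value
        preds.append(lp.argmax(axis=-1).ravel())
        gts.append(
            np.concatenate(
                [s.labels for s in samples[start : start + cfg.batch_size]]
            )
        )
    return iou_recall(np.concatenate(preds), np.concatenate(gts), classes=(0, 1))


def evaluate_alignment(model, samples: list[AlignSample], cfg: TrainConfig):
    """Per-sample residual rotation angle (deg) and point distances (mm)."""
    from .losses import point_set_distance

    angles, d_after, d_before = [], [], []
    i = 0
    for out in _eval_forward(model, samples, cfg, with_fp=False):
        _, R = out
        for b in range(R.value.shape[0]):
            s = samples[i + b]
            Rhat = R.value[b]
            angles.append(np.rad2deg(rotation_angle(Rhat @ s.R_target.T)))
            d_after.append(point_set_distance(s.xyz @ Rhat.T, s.ref))
            d_before.append(point_set_distance(s.xyz, s.ref))
        i += R.value.shape[0]
    return {
        "angle_deg": np.array(angles),
        "dist_after_mm": np.array(d_after),
        "dist_before_mm": np.array(d_before),
    }


def evaluate_landmarks(model, samples: list[LmSample], cfg: TrainConfig):
    """Per-sample, per-marker center errors (mm) from hard-label centroids."""
    from .pipeline import extract_marker_centers

    errors = []   # rows: (scan_id, subject_id, landmark, error_mm or nan)
    accs = []
    i = 0
    for out in _eval_forward(model, samples, cfg, with_fp=True):
        lp = out.value
        for b in range(lp.shape[0]):
            s = samples[i + b]
            cloud = PointCloud(s.xyz)
            pred = extract_marker_centers(lp[b], cloud)
            accs.append(float((lp[b].argmax(axis=-1) == s.labels).mean()))
            for k, name in enumerate(LANDMARK_NAMES):
                if not s.present[k]:
                    continue
                err = (
                    float(np.linalg.norm(pred[name] - s.gt_centers[k]))
                    if name in pred
                    else np.nan
                )
                errors.append((s.scan_id, s.subject_id, name, err))
        i += lp.shape[0]
    import pandas as pd

    return (
        pd.DataFrame(errors, columns=["scan_id", "subject_id", "landmark", "error_mm"]),
        float(np.mean(accs)),
    )
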