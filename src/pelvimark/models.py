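"""Model-facing operations: build networks, run forward passes, checkpoints.

Wraps the `pelvimark.nn` stack behind cloud-level calls: per-point
log-probability prediction for the ROI and landmark segmentation heads, and
rotation prediction (with the mandatory projection onto the rotation group)
for the alignment head.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .geometry import PointCloud, svd_project
from .nn import (
    AlignmentNet,
    PointHierarchy,
    SegmentationNet,
    align_config,
    seg_config,
    stack_hierarchies,
)
from .nn.configs import AlignmentBackboneConfig, SegmentationBackboneConfig

__all__ = [
    "build_roinet",
    "build_landmarknet",
    "build_alignnet",
    "segment_points",
    "predict_rotation",
    "landmark_head",
    "save_model",
    "load_model",
]

N_LANDMARK_CLASSES = 7  # background + six markers


def build_roinet(preset: str = "tiny", seed: int = 0) -> SegmentationNet:
    """Binary pelvic-ROI segmentation network (classes: other / pelvic)."""
    return SegmentationNet(seg_config(2, preset), seed=seed)


def build_landmarknet(preset: str = "tiny", seed: int = 0) -> SegmentationNet:
    """7-class landmark-region network (background + the six markers)."""
    return SegmentationNet(seg_config(N_LANDMARK_CLASSES, preset), seed=seed)


def build_alignnet(preset: str = "tiny", seed: int = 0) -> AlignmentNet:
    """Rotation-regression network with in-forward rotation projection."""
    return AlignmentNet(align_config(preset), seed=seed)


def _require_features(cloud: PointCloud) -> np.ndarray:
    if cloud.features is None or cloud.features.shape[1] != 6:
        raise ValueError(
            "cloud must carry the six per-point feature channels "
            "(see preprocessing.build_point_features)"
        )
    return cloud.features


def segment_points(
    model: SegmentationNet, cloud: PointCloud, sampling_seed: int = 0
) -> np.ndarray:
    """Per-point class log-probabilities (N x C), row-aligned with the cloud."""
    feats = _require_features(cloud)
    model.set_training(False)
    h = PointHierarchy(cloud.positions, model.config.stages, sampling_seed, with_fp=True)
    out = model.forward(feats[None], stack_hierarchies([h]))
    return out.value[0]


def landmark_head(
    model: SegmentationNet, cloud: PointCloud, sampling_seed: int = 0
) -> np.ndarray:
    """Per-point log-probabilities over the 7 landmark classes (N x 7)."""
    if model.config.n_classes != N_LANDMARK_CLASSES:
        raise ValueError(
            f"landmark head requires {N_LANDMARK_CLASSES} classes, "
            f"model has {model.config.n_classes}"
        )
    return segment_points(model, cloud, sampling_seed)


def predict_rotation(
    model: AlignmentNet, cloud: PointCloud, sampling_seed: int = 0
) -> np.ndarray:
    """Predicted rotation matrix (orthonormal, det +1) for a cloud."""
    feats = _require_features(cloud)
    model.set_training(False)
    h = PointHierarchy(cloud.positions, model.config.stages, sampling_seed, with_fp=False)
    M, _ = model.forward(feats[None], stack_hierarchies([h]))
    return svd_project(M.value[0])


# ---------------------------------------------------------------------------
# checkpoints


def _config_record(model) -> dict:
    cfg = model.config
    if isinstance(cfg, SegmentationBackboneConfig):
        kind = "segmentation"
    elif isinstance(cfg, AlignmentBackboneConfig):
        kind = "alignment"
    else:  # pragma: no cover
        raise TypeError(f"unknown config type {type(cfg)}")
    from dataclasses import asdict

    return {"kind": kind, "config": asdict(cfg), "config_hash": cfg.config_hash()}


def save_model(model, path: str | Path) -> None:
    """Save weights (npz) with the config and its hash alongside (json)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = model.state_arrays()
    np.savez(path.with_suffix(".npz"), *arrays)
    path.with_suffix(".json").write_text(json.dumps(_config_record(model), indent=2))


def _config_from_record(rec: dict):
    from .nn.configs import SAScale, SAStageConfig

    c = rec["config"]
    stages = tuple(
        SAStageConfig(
            st["npoint"],
            tuple(SAScale(sc["radius"], sc["k"], tuple(sc["mlp"])) for sc in st["scales"]),
        )
        for st in c["stages"]
    )
    if rec["kind"] == "segmentation":
        return SegmentationBackboneConfig(
            stages=stages,
            fp_mlps=tuple(tuple(m) for m in c["fp_mlps"]),
            head=tuple(c["head"]),
            n_classes=c["n_classes"],
            in_channels=c["in_channels"],
            dropout=c["dropout"],
        )
    return AlignmentBackboneConfig(
        stages=stages,
        global_mlp=tuple(c["global_mlp"]),
        fc=tuple(c["fc"]),
        in_channels=c["in_channels"],
    )


def load_model(path: str | Path):
    """Load a checkpoint saved by :func:`save_model`."""
    path = Path(path)
    rec = json.loads(path.with_suffix(".json").read_text())
    cfg = _config_from_record(rec)
    if cfg.config_hash() != rec["config_hash"]:
        raise ValueError("config hash mismatch in checkpoint")
    model = (
        SegmentationNet(cfg) if rec["kind"] == "segmentation" else AlignmentNet(cfg)
    )
    with np.load(path.with_suffix(".npz")) as data:
        model.load_state_arrays([data[k] for k in data.files])
    model.set_training(False)
    return model
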