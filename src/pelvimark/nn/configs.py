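"""Layer-topology configurations for the three network stages.

The segmentation backbone is a set-abstraction / feature-propagation (SA/FP)
hierarchy: SA stages downsample the cloud by farthest-point sampling and
aggregate local neighbourhoods through shared pointwise MLPs (multi-scale
grouping = several radii per stage, concatenated); FP stages interpolate
features back up and refine them.  The alignment backbone stacks SA stages,
a global aggregation, and fully connected layers emitting a 3x3 matrix that
is projected onto the rotation group inside the forward pass.

The ``full`` presets mirror the canonical published segmentation
architecture at the stage sizes used by the pipeline (1024/256/64/16 points,
512-d deepest features, 128-d per-point output); the ``tiny`` presets are
first-class scaled-down configurations that train in seconds on a CPU and
are used by the test-scale experiments.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

__all__ = [
    "SAScale",
    "SAStageConfig",
    "SegmentationBackboneConfig",
    "AlignmentBackboneConfig",
    "seg_config",
    "align_config",
]


@dataclass(frozen=True)
class SAScale:
    """One grouping scale: ball radius (mm), neighbours, MLP widths."""

    radius: float
    k: int
    mlp: tuple[int, ...]


@dataclass(frozen=True)
class SAStageConfig:
    npoint: int
    scales: tuple[SAScale, ...]

    @property
    def out_channels(self) -> int:
        return sum(s.mlp[-1] for s in self.scales)


@dataclass(frozen=True)
class SegmentationBackboneConfig:
    """SA/FP segmentation network configuration."""

    stages: tuple[SAStageConfig, ...]
    fp_mlps: tuple[tuple[int, ...], ...]  # deepest-to-shallowest
    head: tuple[int, ...]
    n_classes: int
    in_channels: int = 6  # raw xyz + bbox-normalized xyz
    dropout: float = 0.5

    def __post_init__(self):
        counts = [s.npoint for s in self.stages]
        if any(a <= b for a, b in zip(counts, counts[1:])):
            raise ValueError(f"stage point counts must be strictly decreasing, got {counts}")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if len(self.fp_mlps) != len(self.stages):
            raise ValueError("one FP stage per SA stage is required")

    @property
    def min_points(self) -> int:
        return self.stages[-1].npoint

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=list).encode()
        ).hexdigest()[:16]


@dataclass(frozen=True)
class AlignmentBackboneConfig:
    """SA + global-aggregation + FC rotation-regression configuration."""

    stages: tuple[SAStageConfig, ...]
    global_mlp: tuple[int, ...]
    fc: tuple[int, ...]  # hidden FC widths; a final 9-unit layer is implied
    in_channels: int = 6

    def __post_init__(self):
        counts = [s.npoint for s in self.stages]
        if any(a <= b for a, b in zip(counts, counts[1:])):
            raise ValueError(f"stage point counts must be strictly decreasing, got {counts}")

    @property
    def min_points(self) -> int:
        return self.stages[-1].npoint

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=list).encode()
        ).hexdigest()[:16]


def seg_config(n_classes: int, preset: str = "tiny") -> SegmentationBackboneConfig:
    """Segmentation backbone presets.

    ``full`` — stage sizes 1024/256/64/16 with two grouping scales per stage,
    512-d deepest features and a 128-d per-point head, for production-scale
    clouds (16,384 points).  ``tiny`` — 256/64/32/8 single-scale stages for
    2,048-point clouds; trains on a single CPU in seconds per epoch.
    """
    if preset == "full":
        stages = (
            SAStageConfig(1024, (SAScale(25.0, 16, (32, 32, 64)), SAScale(50.0, 32, (32, 48, 64)))),
            SAStageConfig(256, (SAScale(50.0, 16, (64, 64, 128)), SAScale(100.0, 32, (64, 96, 128)))),
            SAStageConfig(64, (SAScale(100.0, 16, (128, 128, 256)),)),
            SAStageConfig(16, (SAScale(200.0, 16, (256, 256, 512)),)),
        )
        fp_mlps = ((256, 256), (256, 256), (256, 128), (128, 128))
        head = (128,)
    elif preset == "tiny":
        stages = (
            SAStageConfig(256, (SAScale(40.0, 12, (32, 32)),)),
            SAStageConfig(64, (SAScale(80.0, 12, (48, 64)),)),
            SAStageConfig(32, (SAScale(160.0, 8, (64, 64)),)),
            SAStageConfig(8, (SAScale(320.0, 8, (64, 128)),)),
        )
        fp_mlps = ((96, 96), (96, 96), (64, 64), (64, 64))
        head = (64,)
    else:
        raise ValueError(f"unknown preset {preset!r}")
    return SegmentationBackboneConfig(stages=stages, fp_mlps=fp_mlps, head=head, n_classes=n_classes)


def align_config(preset: str = "tiny") -> AlignmentBackboneConfig:
    """Alignment backbone presets (512/128-point stages in ``full``)."""
    if preset == "full":
        stages = (
            SAStageConfig(512, (SAScale(50.0, 32, (64, 64, 128)),)),
            SAStageConfig(128, (SAScale(100.0, 32, (128, 128, 256)),)),
        )
        global_mlp = (256, 512)
        fc = (256, 64)
    elif preset == "tiny":
        stages = (
            SAStageConfig(128, (SAScale(60.0, 12, (32, 64)),)),
            SAStageConfig(32, (SAScale(150.0, 8, (64, 96)),)),
        )
        global_mlp = (128, 192)
        fc = (96, 48)
    else:
        raise ValueError(f"unknown preset {preset!r}")
    return AlignmentBackboneConfig(stages=stages, global_mlp=global_mlp, fc=fc)
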