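"""Set-abstraction / feature-propagation point networks.

The geometric scaffolding of a forward pass — farthest-point sampling,
ball-query neighbourhoods and 3-NN interpolation — depends only on the
point coordinates, never on trainable parameters, so it is precomputed per
cloud into a :class:`PointHierarchy` (seeded, hence deterministic) and can
be cached across epochs.  The trainable part then reduces to dense tensor
operations on the autodiff graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .autodiff import Tensor, concat
from .configs import AlignmentBackboneConfig, SegmentationBackboneConfig
from .layers import Dropout, Linear, MLP, Module

__all__ = [
    "ArchitectureConstraintError",
    "farthest_point_sample",
    "ball_neighbors",
    "PointHierarchy",
    "stack_hierarchies",
    "SegmentationNet",
    "AlignmentNet",
    "polar_project_newton",
]


class ArchitectureConstraintError(ValueError):
    """Input violates a structural requirement of the network."""


def farthest_point_sample(xyz: np.ndarray, m: int, rng: np.random.Generator) -> np.ndarray:
    """Indices of ``m`` points chosen by iterative farthest-point selection."""
    n = xyz.shape[0]
    if m > n:
        raise ArchitectureConstraintError(f"cannot sample {m} from {n} points")
    idx = np.empty(m, dtype=np.int64)
    idx[0] = rng.integers(n)
    d = np.linalg.norm(xyz - xyz[idx[0]], axis=1)
    for i in range(1, m):
        idx[i] = int(d.argmax())
        d = np.minimum(d, np.linalg.norm(xyz - xyz[idx[i]], axis=1))
    return idx


def ball_neighbors(
    tree: cKDTree, xyz: np.ndarray, centers: np.ndarray, radius: float, k: int
) -> np.ndarray:
    """For each center, ``k`` nearest neighbours within ``radius`` (m x k).

    Centers with fewer than ``k`` in-ball neighbours repeat their nearest
    point, so every row is fully populated (standard ball-query padding).
    """
    n = xyz.shape[0]
    dist, idx = tree.query(centers, k=k, distance_upper_bound=radius)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    missing = idx >= n
    if missing.any():
        _, nearest = tree.query(centers, k=1)
        nearest = np.atleast_1d(nearest)
        fill = np.broadcast_to(nearest[:, None], idx.shape)
        idx = np.where(missing, fill, idx)
    return idx.astype(np.int64)


@dataclass
class _SALevel:
    center_idx: np.ndarray          # (m,) into previous level
    xyz: np.ndarray                 # (m, 3)
    neighbor_idx: list[np.ndarray]  # per scale, (m, k) into previous level
    rel_xyz: list[np.ndarray]       # per scale, (m, k, 3), radius-normalized


@dataclass
class _FPLevel:
    idx: np.ndarray      # (n_fine, 3) into coarse level
    weights: np.ndarray  # (n_fine, 3), inverse-distance, normalized


class PointHierarchy:
    """Per-cloud sampling/grouping structure for a backbone configuration."""

    def __init__(self, xyz: np.ndarray, stages, seed: int, with_fp: bool):
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape[0] < stages[-1].npoint:
            raise ArchitectureConstraintError(
                f"cloud has {xyz.shape[0]} points; deepest stage needs {stages[-1].npoint}"
            )
        rng = np.random.default_rng(seed)
        self.level_xyz = [xyz]
        self.sa: list[_SALevel] = []
        prev = xyz
        for st in stages:
            cidx = farthest_point_sample(prev, st.npoint, rng)
            centers = prev[cidx]
            tree = cKDTree(prev)
            neigh, rel = [], []
            for sc in st.scales:
                ni = ball_neighbors(tree, prev, centers, sc.radius, sc.k)
                neigh.append(ni)
                rel.append((prev[ni] - centers[:, None, :]) / sc.radius)
            self.sa.append(_SALevel(cidx, centers, neigh, rel))
            self.level_xyz.append(centers)
            prev = centers
        self.fp: list[_FPLevel] = []
        self.level0_geo: np.ndarray | None = None
        if with_fp:
            # deepest-to-shallowest: coarse level i+1 interpolated onto level i
            for i in range(len(stages) - 1, -1, -1):
                fine, coarse = self.level_xyz[i], self.level_xyz[i + 1]
                kk = min(3, coarse.shape[0])
                dist, idx = cKDTree(coarse).query(fine, k=kk)
                if kk == 1:
                    dist, idx = dist[:, None], idx[:, None]
                w = 1.0 / np.maximum(dist, 1e-8)
                w = w / w.sum(axis=1, keepdims=True)
                if kk < 3:  # pad to a fixed width of 3
                    pad = 3 - kk
                    idx = np.concatenate([idx, np.repeat(idx[:, :1], pad, axis=1)], axis=1)
                    w = np.concatenate([w, np.zeros((w.shape[0], pad))], axis=1)
                self.fp.append(_FPLevel(idx.astype(np.int64), w))
            self.level0_geo = _local_plane_descriptor(xyz)


def _local_plane_descriptor(
    xyz: np.ndarray, scales: tuple[tuple[int, float], ...] = ((12, 20.0), (24, 40.0))
) -> np.ndarray:
    """Point-resolution geometric channels from multi-scale plane fits (N, 3*S).

    For each point's neighbourhood (k nearest within ``radius`` mm, one
    (k, radius) pair per scale) a plane is fitted by PCA; the channels are
    the point's signed height above the plane (bump/dimple indicator, sign
    fixed to the +z hemisphere), the neighbourhood roughness
    (smallest-eigenvalue scale) and the tilt of the local normal.  The small
    scale resolves dimples, the larger one ridge-scale curvature.  Computed
    once per cloud; not trainable.
    """
    n = xyz.shape[0]
    tree = cKDTree(xyz)
    out = []
    for k, radius in scales:
        kk = min(k, n)
        dist, idx = tree.query(xyz, k=kk)
        if kk == 1:
            out.append(np.zeros((n, 3)))
            continue
        valid = dist <= radius
        valid[:, 0] = True
        w = valid.astype(float)
        w /= w.sum(axis=1, keepdims=True)
        nbr = xyz[idx]                                     # (N, k, 3)
        mean = (nbr * w[..., None]).sum(axis=1)            # (N, 3)
        cent = (nbr - mean[:, None, :]) * valid[..., None]
        cov = np.einsum("nki,nkj->nij", cent, cent) / np.maximum(
            valid.sum(axis=1), 2.0
        )[:, None, None]
        evals, evecs = np.linalg.eigh(cov)
        normal = evecs[:, :, 0]
        normal = np.where(normal[:, 2:3] < 0, -normal, normal)  # +z hemisphere
        height = ((xyz - mean) * normal).sum(axis=1)
        rough = np.sqrt(np.maximum(evals[:, 0], 0.0))
        tilt = 1.0 - np.abs(normal[:, 2])
        out.append(np.stack([height, rough, tilt], axis=1))
    return np.concatenate(out, axis=1)

N_GEO_CHANNELS = 6


@dataclass
class StackedHierarchy:
    """Batch-stacked hierarchy arrays (all clouds share N and the config)."""

    sa_neighbors: list[list[np.ndarray]]  # [stage][scale] (B, m, k)
    sa_rel: list[list[np.ndarray]]        # [stage][scale] (B, m, k, 3)
    fp_idx: list[np.ndarray]              # [fp step] (B, n_fine, 3)
    fp_w: list[np.ndarray]                # [fp step] (B, n_fine, 3)
    level_xyz: list[np.ndarray]           # [level] (B, m, 3)
    level0_geo: np.ndarray | None = None  # (B, N, 6) local-plane descriptor


def stack_hierarchies(hs: list[PointHierarchy]) -> StackedHierarchy:
    n_stage = len(hs[0].sa)
    sa_neighbors = [
        [np.stack([h.sa[s].neighbor_idx[sc] for h in hs]) for sc in range(len(hs[0].sa[s].neighbor_idx))]
        for s in range(n_stage)
    ]
    sa_rel = [
        [np.stack([h.sa[s].rel_xyz[sc] for h in hs]) for sc in range(len(hs[0].sa[s].rel_xyz))]
        for s in range(n_stage)
    ]
    fp_idx = [np.stack([h.fp[i].idx for h in hs]) for i in range(len(hs[0].fp))]
    fp_w = [np.stack([h.fp[i].weights for h in hs]) for i in range(len(hs[0].fp))]
    level_xyz = [np.stack([h.level_xyz[i] for h in hs]) for i in range(len(hs[0].level_xyz))]
    geo = (
        np.stack([h.level0_geo for h in hs]) if hs[0].level0_geo is not None else None
    )
    return StackedHierarchy(sa_neighbors, sa_rel, fp_idx, fp_w, level_xyz, geo)


def _sa_forward(stage_mlps, feats: Tensor, neigh, rel) -> Tensor:
    """One SA stage: gather neighbourhoods, shared MLP, max-pool, concat scales."""
    outs = []
    for mlp, ni, rx in zip(stage_mlps, neigh, rel):
        grouped = feats.gather(ni, batched=True)          # (B, m, k, F)
        grouped = concat([Tensor(rx), grouped], axis=-1)  # + relative coords
        outs.append(mlp(grouped).max(axis=2))             # (B, m, F')
    return concat(outs, axis=-1) if len(outs) > 1 else outs[0]


def _fp_forward(mlp, coarse_feats: Tensor, skip_feats: Tensor | None, idx, w) -> Tensor:
    """One FP stage: 3-NN inverse-distance interpolation + skip concat + MLP."""
    gathered = coarse_feats.gather(idx, batched=True)        # (B, n, 3, F)
    interp = (gathered * w[..., None]).sum(axis=2)           # (B, n, F)
    if skip_feats is not None:
        interp = concat([skip_feats, interp], axis=-1)
    return mlp(interp)


class SegmentationNet(Module):
    """SA/FP per-point classifier emitting log-probabilities (B, N, C)."""

    def __init__(self, config: SegmentationBackboneConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        self.sa_mlps: list[list[MLP]] = []
        c_prev = config.in_channels
        self.level_channels = [c_prev]
        for st in config.stages:
            mlps = [self.register(MLP(c_prev + 3, sc.mlp, rng)) for sc in st.scales]
            self.sa_mlps.append(mlps)
            c_prev = st.out_channels
            self.level_channels.append(c_prev)
        self.fp_mlps: list[MLP] = []
        c_above = self.level_channels[-1]
        for step, widths in enumerate(config.fp_mlps):
            skip_level = len(config.stages) - 1 - step
            c_in = c_above + self.level_channels[skip_level]
            if skip_level == 0:
                c_in += N_GEO_CHANNELS  # level-0 local-plane descriptor channels
            m = self.register(MLP(c_in, widths, rng))
            self.fp_mlps.append(m)
            c_above = widths[-1]
        self.head_mlp = self.register(MLP(c_above, config.head, rng))
        self.dropout = self.register(Dropout(config.dropout, np.random.default_rng(seed + 1)))
        self.out = self.register(Linear(config.head[-1], config.n_classes, rng))

    def forward(self, features: np.ndarray | Tensor, h: StackedHierarchy) -> Tensor:
        x = features if isinstance(features, Tensor) else Tensor(features)
        level_feats: list[Tensor] = [x]
        for s, mlps in enumerate(self.sa_mlps):
            x = _sa_forward(mlps, x, h.sa_neighbors[s], h.sa_rel[s])
            level_feats.append(x)
        for step, mlp in enumerate(self.fp_mlps):
            skip_level = len(self.sa_mlps) - 1 - step
            skip = level_feats[skip_level]
            if skip_level == 0 and h.level0_geo is not None:
                skip = concat([skip, Tensor(h.level0_geo)], axis=-1)
            x = _fp_forward(mlp, x, skip, h.fp_idx[step], h.fp_w[step])
        x = self.dropout(self.head_mlp(x))
        return self.out(x).log_softmax(axis=-1)


def _transpose_last2(t: Tensor) -> Tensor:
    axes = list(range(t.value.ndim))
    axes[-1], axes[-2] = axes[-2], axes[-1]
    return t.transpose(*axes)


def polar_project_newton(M: Tensor, iters: int = 14) -> Tensor:
    """Differentiable projection of (..., 3, 3) matrices onto the rotation group.

    Newton iteration for the orthogonal polar factor,
    ``X <- (X + X^-T) / 2``, after Frobenius pre-scaling.  Valid for inputs
    with positive determinant (maintained during training by identity
    initialization plus the orthonormality regularizer); inference uses the
    exact SVD projection instead.
    """
    s = ((M * M).sum(axis=(-2, -1), keepdims=True) / 3.0 + 1e-12).sqrt()
    X = M / s
    for _ in range(iters):
        X = (X + _transpose_last2(X.inv3())) * 0.5
    return X


def _pca_frames(xyz: np.ndarray) -> np.ndarray:
    """Deterministic per-cloud sheet frames (B, 3, 3); columns are the
    estimated (lateral, vertical, depth) axes in input coordinates.

    The depth axis is the smallest covariance eigenvector of the
    outlier-trimmed centred cloud — the posterior trunk patch is thin in
    depth, and this axis is pose-equivariant and stable across subjects
    (unlike the in-plane eigenvectors, whose direction swings tens of
    degrees with posture and crop shape).  The vertical axis is the world +y
    direction projected into the sheet plane, and the lateral axis completes
    a right-handed frame.  Expressing the cloud in this frame removes the
    two out-of-plane pose degrees of freedom analytically; the network head
    only has to estimate the remaining in-plane rotation and the small
    subject-specific tilt of the canonical frame.  The depth-axis sign
    (+z hemisphere) relies on the acquisition protocol's bounded pose.
    """
    frames = []
    for b in range(xyz.shape[0]):
        p = xyz[b] - xyz[b].mean(axis=0)
        d = np.linalg.norm(p, axis=1)
        p = p[d <= 2.2 * np.median(d)]
        cov = p.T @ p / p.shape[0]
        _, V = np.linalg.eigh(cov)  # ascending eigenvalues
        a_depth = V[:, 0] * (1.0 if V[2, 0] >= 0 else -1.0)
        y_proj = np.array([0.0, 1.0, 0.0]) - a_depth[1] * a_depth
        a_vert = y_proj / np.linalg.norm(y_proj)
        a_lat = np.cross(a_vert, a_depth)
        frames.append(np.stack([a_lat, a_vert, a_depth], axis=1))
    return np.stack(frames)


def _moment_descriptor(xyz: np.ndarray, scale: float, frames: np.ndarray | None = None) -> np.ndarray:
    """Orientation-sensitive global moments of a (B, N, 3) cloud.

    First moments, the six unique second moments and all ten unique third
    moments of the normalized coordinates, plus trace-normalized
    (scale-invariant) copies.  With ``frames`` supplied the coordinates are
    first expressed in each cloud's own PCA frame, which makes the whole
    descriptor rotation-invariant — the right input for predicting the
    frame-to-canonical residual.
    """
    descs = []
    for b in range(xyz.shape[0]):
        p = xyz[b] / scale
        # robust trim: drop far outliers (stray limb/shoulder points leaking
        # through an imperfect ROI mask distort the moments badly)
        d = np.linalg.norm(p - p.mean(axis=0), axis=1)
        p = p[d <= 2.2 * np.median(d)]
        if frames is not None:
            p = p @ frames[b]
        m1 = p.mean(axis=0)                               # (3,)
        outer = p.T @ p / p.shape[0]                      # (3, 3)
        iu = np.triu_indices(3)
        m2 = outer[iu]                                    # (6,)
        m3 = np.array(
            [
                (p[:, i] * p[:, j] * p[:, k]).mean()
                for i in range(3)
                for j in range(i, 3)
                for k in range(j, 3)
            ]
        )                                                 # (10,)
        # scale-invariant copies: normalized by the trace of the second
        # moment, so subject size does not confound the decoding
        tr = np.trace(outer) + 1e-12
        descs.append(np.concatenate([m1, m2, m3, m2 / tr, m3 / tr**1.5]))
    return np.stack(descs)                                # (B, 35)


class AlignmentNet(Module):
    """SA stages + global aggregation + FC regression of a 3x3 matrix.

    The forward pass factors the pose analytically: a deterministic,
    rotation-equivariant PCA frame of the input cloud carries the bulk of
    the orientation, and the network head predicts only the small residual
    between that frame and the subject's canonical frame.  The residual is
    decoded from rotation-invariant inputs — max/mean-pooled learned
    features plus coordinate moments expressed in the PCA frame — so it
    generalizes across poses by construction.  ``forward`` returns the raw
    predicted matrix (frame times residual) and its projection onto the
    rotation group (the projection is part of the forward pass).
    """

    #: scale (mm) used to normalize absolute coordinates fed to the global MLP
    GLOBAL_XYZ_SCALE = 300.0

    def __init__(self, config: AlignmentBackboneConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        self.sa_mlps: list[list[MLP]] = []
        c_prev = config.in_channels
        for st in config.stages:
            mlps = [self.register(MLP(c_prev + 3, sc.mlp, rng)) for sc in st.scales]
            self.sa_mlps.append(mlps)
            c_prev = st.out_channels
        self.global_mlp = self.register(MLP(c_prev + 3, config.global_mlp, rng))
        # 35 raw + 35 sheet-frame moments + the 9 frame entries
        self.fc = self.register(MLP(2 * config.global_mlp[-1] + 79, config.fc, rng))
        self.out = self.register(Linear(config.fc[-1], 9, rng))
        # identity initialization keeps det(M) > 0 from the first step
        self.out.w.value *= 0.01
        self.out.b.value = np.eye(3).ravel().copy()

    def forward(self, features: np.ndarray | Tensor, h: StackedHierarchy):
        x = features if isinstance(features, Tensor) else Tensor(features)
        for s, mlps in enumerate(self.sa_mlps):
            x = _sa_forward(mlps, x, h.sa_neighbors[s], h.sa_rel[s])
        xyz_last = h.level_xyz[len(self.sa_mlps)] / self.GLOBAL_XYZ_SCALE
        x = concat([Tensor(xyz_last), x], axis=-1)
        x = self.global_mlp(x)
        frames = _pca_frames(h.level_xyz[0])
        moments = _moment_descriptor(h.level_xyz[0], self.GLOBAL_XYZ_SCALE)
        frame_moments = _moment_descriptor(h.level_xyz[0], self.GLOBAL_XYZ_SCALE, frames)
        x = concat(
            [
                x.max(axis=1),
                x.mean(axis=1),
                Tensor(moments),
                Tensor(frame_moments),
                Tensor(frames.reshape(frames.shape[0], 9)),
            ],
            axis=-1,
        )
        x = self.fc(x)
        M = self.out(x).reshape(-1, 3, 3)
        return M, polar_project_newton(M)
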