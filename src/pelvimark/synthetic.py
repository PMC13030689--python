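"""Deterministic generator of pelvic-like surface scans with landmarks.

The generator emulates structured-light back/pelvis surface scans: a smooth
parametric sheet ``z = f(x, y)`` (elliptical trunk cross-section with a
spinal groove, lumbar bulge, PSIS dimples and iliac-crest ridges) sampled to
a target point count, with Gaussian sensor noise along surface normals,
optional acquisition artifacts (contiguous occlusion patches, limb
fragments), rigid scanner-frame pose, and two postures — upright (P1) and a
forward bend (P2) modelled as an extra depth curvature above the waist.

Six ground-truth landmarks (PSIS_L/R, IC_L/R, L1, L4) are placed on the
parametric surface from a per-subject template; every scan is a pure
function of its recipe and seed.  Anatomically validated human shape
modelling and soft-tissue deformation physics are out of scope: the surface
provides the *statistical* structure the pipeline needs (local curvature
cues at the markers, global posture variation, artifacts), not an
anthropometric model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    LandmarkSet,
    PointCloud,
    RigidTransform,
    canonicalize_pose,
    rotation_from_euler,
)

__all__ = [
    "SubjectShape",
    "ScanRecipe",
    "ScanRecord",
    "sample_subject",
    "generate_scan",
    "generate_dataset",
    "POINT_RANGE",
]

#: target per-scan point counts: full-resolution scans and the test-scale preset
POINT_RANGE = {"full": (200_000, 600_000), "tiny": (20_000, 60_000)}


@dataclass(frozen=True)
class SubjectShape:
    """Per-subject parameters of the parametric back/pelvis surface (mm)."""

    half_width: float          # trunk half-width at the hips
    depth_amplitude: float     # maximal depth of the trunk cross-section
    lumbar_amplitude: float    # extra depth of the lumbar bulge
    groove_depth: float        # spinal groove depth
    groove_sigma: float        # spinal groove lateral spread
    dimple_depth: float        # PSIS dimple depth
    psis_half_sep: float       # half the PSIS_L-PSIS_R separation
    ic_height: float           # iliac-crest marker height above the PSIS level
    ic_lateral_frac: float     # IC marker lateral position as fraction of width
    l4_height: float           # L4 marker height above the PSIS level
    l1_offset: float           # L1 height above L4
    y_range: tuple[float, float] = (-250.0, 420.0)

    def template_landmarks(self) -> dict[str, tuple[float, float]]:
        """(x, y) positions of the six markers on the parametric sheet."""
        x_ic = self.ic_lateral_frac * self.half_width
        return {
            "PSIS_L": (-self.psis_half_sep, 0.0),
            "PSIS_R": (+self.psis_half_sep, 0.0),
            "IC_L": (-x_ic, self.ic_height),
            "IC_R": (+x_ic, self.ic_height),
            "L1": (0.0, self.l4_height + self.l1_offset),
            "L4": (0.0, self.l4_height),
        }


@dataclass
class ScanRecipe:
    """Everything needed to synthesize one scan deterministically."""

    shape: SubjectShape
    posture: str = "P1"            # "P1" upright | "P2" forward bend
    n_points: int = 40_000
    noise_sigma: float = 1.0       # mm, along surface normals
    bend_angle_deg: float = 30.0   # P2 forward-bend magnitude
    occlusion: bool = False
    occlusion_fraction: float = 0.05
    limb_fragment: bool = False
    pose_rotation_deg: float = 15.0    # scanner-frame pose jitter, per axis
    pose_translation_mm: float = 50.0
    landmark_jitter_mm: float = 0.0    # palpation/digitization variability
    seed: int = 0

    def __post_init__(self):
        if self.n_points < 100:
            raise ValueError("n_points too small for a surface scan")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.posture not in ("P1", "P2"):
            raise ValueError("posture must be 'P1' or 'P2'")


@dataclass
class ScanRecord:
    """One generated scan with full provenance metadata."""

    cloud: PointCloud
    landmarks: LandmarkSet
    subject_id: str
    visit: int
    repeat: int
    posture: str


def sample_subject(seed: int) -> SubjectShape:
    """Draw a plausible subject shape; deterministic per seed."""
    rng = np.random.default_rng(seed)
    return SubjectShape(
        half_width=rng.uniform(150.0, 210.0),
        depth_amplitude=rng.uniform(45.0, 75.0),
        lumbar_amplitude=rng.uniform(10.0, 25.0),
        groove_depth=rng.uniform(4.0, 9.0),
        groove_sigma=rng.uniform(10.0, 16.0),
        dimple_depth=rng.uniform(5.0, 9.0),
        psis_half_sep=rng.uniform(32.0, 48.0),
        ic_height=rng.uniform(60.0, 90.0),
        ic_lateral_frac=rng.uniform(0.66, 0.78),
        l4_height=rng.uniform(55.0, 80.0),
        l1_offset=rng.uniform(90.0, 120.0),
    )


# ---------------------------------------------------------------------------
# the parametric surface


def _width_profile(shape: SubjectShape, y: np.ndarray) -> np.ndarray:
    """Trunk half-width as a function of height: hips, waist, shoulders."""
    w = shape.half_width * (
        1.0
        + 0.10 * np.exp(-((y - 0.0) ** 2) / (2 * 90.0**2))      # hips
        - 0.12 * np.exp(-((y - 160.0) ** 2) / (2 * 70.0**2))    # waist
        + 0.15 * np.exp(-((y - 380.0) ** 2) / (2 * 90.0**2))    # shoulders
    )
    return w


def _surface_depth(shape: SubjectShape, x: np.ndarray, y: np.ndarray, bend: float) -> np.ndarray:
    """Depth z of the back surface at sheet coordinates (x, y)."""
    w = _width_profile(shape, y)
    frac = np.clip(x / w, -1.0, 1.0)
    z = shape.depth_amplitude * np.sqrt(np.maximum(0.0, 1.0 - frac**2))
    z = z + shape.lumbar_amplitude * np.exp(-((y - 60.0) ** 2) / (2 * 80.0**2))
    z = z - shape.groove_depth * np.exp(-(x**2) / (2 * shape.groove_sigma**2)) * np.exp(
        -((y - 120.0) ** 2) / (2 * 180.0**2)
    )
    for sx in (-1.0, 1.0):
        # PSIS dimples ("dimples of Venus")
        z = z - shape.dimple_depth * np.exp(
            -(((x - sx * shape.psis_half_sep) ** 2) + y**2) / (2 * 12.0**2)
        )
        # iliac-crest ridges peaking at the marked point
        xi = sx * shape.ic_lateral_frac * shape.half_width
        z = z + shape.dimple_depth * np.exp(
            -(((x - xi) ** 2) / (2 * 16.0**2) + ((y - shape.ic_height) ** 2) / (2 * 10.0**2))
        )
    # palpable spinous prominences at the two marked vertebral levels
    for yl in (shape.l4_height, shape.l4_height + shape.l1_offset):
        z = z + 0.8 * shape.dimple_depth * np.exp(
            -((x**2) / (2 * 9.0**2) + ((y - yl) ** 2) / (2 * 9.0**2))
        )
    if bend != 0.0:
        # forward bend: depth curvature growing above the waist
        lever = np.maximum(0.0, y - 100.0)
        z = z - np.tan(np.deg2rad(bend)) * lever**2 / 400.0
    return z


def _surface_normals(shape: SubjectShape, x: np.ndarray, y: np.ndarray, bend: float) -> np.ndarray:
    eps = 0.5
    fx = (_surface_depth(shape, x + eps, y, bend) - _surface_depth(shape, x - eps, y, bend)) / (2 * eps)
    fy = (_surface_depth(shape, x, y + eps, bend) - _surface_depth(shape, x, y - eps, bend)) / (2 * eps)
    n = np.stack([-fx, -fy, np.ones_like(fx)], axis=1)
    return n / np.linalg.norm(n, axis=1, keepdims=True)


def generate_scan(recipe: ScanRecipe) -> tuple[PointCloud, LandmarkSet]:
    """Synthesize one scan (scanner frame) and its ground-truth landmarks."""
    shape = recipe.shape
    rng = np.random.default_rng(recipe.seed)
    bend = recipe.bend_angle_deg if recipe.posture == "P2" else 0.0

    # landmarks on the sheet, then canonicalized so the PSIS midpoint is at
    # the origin, the PSIS segment horizontal and L4 at zero depth
    lm_xy = shape.template_landmarks()
    raw = LandmarkSet(
        {
            n: (x, y, float(_surface_depth(shape, np.array([x]), np.array([y]), bend)[0]))
            for n, (x, y) in lm_xy.items()
        }
    )
    t_canon = canonicalize_pose(raw)
    landmarks = raw.transform(t_canon)

    # surface sampling: uniform over the sheet, rejecting points beyond the flank
    y_lo, y_hi = shape.y_range
    n_target = recipe.n_points
    xs, ys = [], []
    got = 0
    while got < n_target:
        m = int((n_target - got) * 1.5) + 100
        cand_y = rng.uniform(y_lo, y_hi, size=m)
        w = _width_profile(shape, cand_y)
        cand_x = rng.uniform(-1.0, 1.0, size=m) * shape.half_width * 1.25
        keep = np.abs(cand_x) <= w
        xs.append(cand_x[keep])
        ys.append(cand_y[keep])
        got += int(keep.sum())
    x = np.concatenate(xs)[:n_target]
    y = np.concatenate(ys)[:n_target]
    z = _surface_depth(shape, x, y, bend)
    pts = np.stack([x, y, z], axis=1)

    if recipe.occlusion:
        # remove a contiguous patch: exactly the requested fraction of points
        n_remove = int(round(recipe.occlusion_fraction * pts.shape[0]))
        center = np.array(
            [rng.uniform(-shape.half_width, shape.half_width), rng.uniform(-50.0, 200.0)]
        )
        d2 = ((pts[:, :2] - center) ** 2).sum(axis=1)
        keep_idx = np.argsort(d2)[n_remove:]
        keep_idx.sort()
        pts = pts[keep_idx]
        x, y = pts[:, 0], pts[:, 1]

    if recipe.noise_sigma > 0:
        normals = _surface_normals(shape, x, y, bend)
        pts = pts + normals * rng.normal(0.0, recipe.noise_sigma, size=(pts.shape[0], 1))

    pts = t_canon.apply_points(pts)

    if recipe.limb_fragment:
        # a partially visible upper-limb blob hanging beside the trunk
        side = rng.choice([-1.0, 1.0])
        n_limb = max(200, pts.shape[0] // 50)
        limb_center = np.array([side * (shape.half_width + 80.0), rng.uniform(0.0, 150.0), 20.0])
        limb = limb_center + rng.normal(0.0, 1.0, size=(n_limb, 3)) * np.array([25.0, 90.0, 20.0])
        pts = np.concatenate([pts, limb])

    if recipe.landmark_jitter_mm > 0:
        landmarks = LandmarkSet(
            {
                n: v + rng.normal(0.0, recipe.landmark_jitter_mm, size=3)
                for n, v in landmarks.items()
            }
        )

    # scanner-frame pose
    ang = rng.uniform(-1.0, 1.0, size=3) * np.deg2rad(recipe.pose_rotation_deg)
    trans = rng.uniform(-1.0, 1.0, size=3) * recipe.pose_translation_mm
    pose = RigidTransform(rotation_from_euler(ang), trans)
    pts = pose.apply_points(pts)
    landmarks = landmarks.transform(pose)

    cloud = PointCloud(pts, posture=recipe.posture)
    return cloud, landmarks


def generate_dataset(
    n_subjects: int,
    visits: int = 1,
    repeats_per_visit: int = 2,
    postures: tuple[str, ...] = ("P1", "P2"),
    seed: int = 0,
    preset: str = "tiny",
    noise_sigma: float = 1.0,
    landmark_jitter_mm: float = 2.0,
    artifact_probability: float = 0.15,
) -> list[ScanRecord]:
    """Generate a cohort: subjects x visits x repeats x postures.

    Repeats within a visit share the subject shape and differ only by
    scanner pose, sensor noise and small landmark placement jitter — the
    structure the repeatability analysis assumes.  A random subset of scans
    carries acquisition artifacts (occlusion or a limb fragment).
    """
    if repeats_per_visit not in (2, 3):
        raise ValueError("repeats_per_visit must be 2 or 3")
    lo, hi = POINT_RANGE[preset]
    records: list[ScanRecord] = []
    for s in range(n_subjects):
        shape = sample_subject(int(np.random.default_rng((seed, s, 101)).integers(2**31)))
        for v in range(visits):
            for p in postures:
                for r in range(repeats_per_visit):
                    p_code = {"P1": 1, "P2": 2}.get(p, 9)
                    srng = np.random.default_rng((seed, s, v, r, p_code))
                    recipe = ScanRecipe(
                        shape=shape,
                        posture=p,
                        n_points=int(srng.integers(lo, hi + 1)),
                        noise_sigma=noise_sigma,
                        occlusion=bool(srng.random() < artifact_probability),
                        limb_fragment=bool(srng.random() < artifact_probability),
                        landmark_jitter_mm=landmark_jitter_mm,
                        seed=int(srng.integers(2**31)),
                    )
                    cloud, lms = generate_scan(recipe)
                    cloud.subject_id = f"S{s:03d}"
                    cloud.scan_id = f"S{s:03d}_V{v}_{p}_R{r}"
                    records.append(
                        ScanRecord(
                            cloud=cloud,
                            landmarks=lms,
                            subject_id=f"S{s:03d}",
                            visit=v,
                            repeat=r,
                            posture=p,
                        )
                    )
    return records
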