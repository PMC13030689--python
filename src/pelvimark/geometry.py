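"""Coordinate conventions, rigid transforms and the canonical pelvic pose.

Conventions used throughout the package (all coordinates in millimetres):

* ``x`` — lateral axis (subject's right is +x),
* ``y`` — vertical axis (up is +y),
* ``z`` — depth axis (toward the scanner is +z).

Euler angles are intrinsic x -> y -> z, i.e. a rotation matrix factors as
``R = Rx(tx) @ Ry(ty) @ Rz(tz)``.  The *canonical pose* places the midpoint
of the two posterior superior iliac spines (PSIS) at the origin, makes the
PSIS segment horizontal (zero depth difference) and puts the L4 marker at
zero depth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "LANDMARK_NAMES",
    "PointCloud",
    "LandmarkSet",
    "EulerAngles",
    "RigidTransform",
    "DegenerateGeometryError",
    "InvalidRotationError",
    "MissingLandmarkError",
    "is_rotation_matrix",
    "svd_project",
    "rotation_from_euler",
    "euler_from_rotation",
    "rotation_angle",
    "apply_transform",
    "canonicalize_pose",
]

#: Canonical landmark order; integer region labels 1..6 follow this order.
LANDMARK_NAMES = ("PSIS_L", "PSIS_R", "IC_L", "IC_R", "L1", "L4")

EULER_CONVENTION = "intrinsic-xyz"


class InvalidRotationError(ValueError):
    """A matrix that was required to be a rotation is not one."""


class DegenerateGeometryError(ValueError):
    """Landmark geometry does not determine the requested construction."""


class MissingLandmarkError(KeyError):
    """A required named landmark is absent."""


@dataclass
class PointCloud:
    """N x 3 surface points in mm with optional per-point feature channels."""

    positions: np.ndarray
    features: np.ndarray | None = None
    subject_id: str | None = None
    scan_id: str | None = None
    posture: str | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError(f"positions must be N x 3, got {self.positions.shape}")
        if self.positions.shape[0] < 1:
            raise ValueError("point cloud must contain at least one point")
        if not np.isfinite(self.positions).all():
            raise ValueError("positions contain non-finite values")
        if self.features is not None:
            self.features = np.asarray(self.features, dtype=float)
            if self.features.shape[0] != self.positions.shape[0]:
                raise ValueError("features must be row-aligned with positions")

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def n_points(self) -> int:
        return self.positions.shape[0]

    def subset(self, index: np.ndarray) -> "PointCloud":
        """Row-subset positions (and features) by an index array or mask."""
        feats = None if self.features is None else self.features[index]
        return replace(self, positions=self.positions[index], features=feats)


class LandmarkSet(Mapping):
    """Named 3D coordinates of the six posterior pelvic markers (mm).

    Keys are restricted to :data:`LANDMARK_NAMES`; a marker may be absent
    (e.g. not predicted), in which case it simply has no entry.
    """

    def __init__(self, coords: Mapping[str, np.ndarray] | None = None, **kw):
        self._coords: dict[str, np.ndarray] = {}
        merged = dict(coords or {})
        merged.update(kw)
        for name, xyz in merged.items():
            self[name] = xyz

    def __setitem__(self, name: str, xyz) -> None:
        if name not in LANDMARK_NAMES:
            raise KeyError(f"unknown landmark name {name!r}; expected one of {LANDMARK_NAMES}")
        arr = np.asarray(xyz, dtype=float).reshape(3)
        if not np.isfinite(arr).all():
            raise ValueError(f"landmark {name} has non-finite coordinates")
        self._coords[name] = arr

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self._coords[name]
        except KeyError:
            raise MissingLandmarkError(name) from None

    def __iter__(self):
        return iter([n for n in LANDMARK_NAMES if n in self._coords])

    def __len__(self) -> int:
        return len(self._coords)

    def __contains__(self, name) -> bool:
        return name in self._coords

    def __repr__(self) -> str:
        inner = ", ".join(f"{n}={np.round(v, 2).tolist()}" for n, v in self.items())
        return f"LandmarkSet({inner})"

    def as_array(self, names=LANDMARK_NAMES) -> np.ndarray:
        """Stack the named (present) landmarks into a len(names) x 3 array."""
        return np.stack([self[n] for n in names])

    def transform(self, t: "RigidTransform") -> "LandmarkSet":
        return LandmarkSet({n: t.apply_points(v[None])[0] for n, v in self.items()})


@dataclass(frozen=True)
class EulerAngles:
    """Intrinsic x->y->z Euler angles in radians, each in (-pi, pi]."""

    tx: float
    ty: float
    tz: float
    convention: str = EULER_CONVENTION

    def as_array(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz])


def is_rotation_matrix(R: np.ndarray, tol: float = 1e-6) -> bool:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3) or not np.isfinite(R).all():
        return False
    return (
        np.linalg.norm(R.T @ R - np.eye(3)) < tol
        and abs(np.linalg.det(R) - 1.0) < tol
    )


def _check_rotation(R: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if not is_rotation_matrix(R, tol):
        raise InvalidRotationError(
            "matrix is not orthonormal with det +1 "
            f"(residual {np.linalg.norm(R.T @ R - np.eye(3)):.2e}, det {np.linalg.det(R):.6f})"
        )
    return R


@dataclass
class RigidTransform:
    """Rigid map ``p -> R p + t`` acting about the global origin."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def apply_points(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equal to *self after other* (self ∘ other)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    # -- flat JSON record ------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "rotation": [float(v) for v in self.rotation.ravel()],
                "translation": [float(v) for v in self.translation],
                "euler_convention": EULER_CONVENTION,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "RigidTransform":
        rec = json.loads(text)
        if rec.get("euler_convention", EULER_CONVENTION) != EULER_CONVENTION:
            raise ValueError(f"unsupported euler convention {rec['euler_convention']!r}")
        return cls(
            np.array(rec["rotation"], dtype=float).reshape(3, 3),
            np.array(rec["translation"], dtype=float),
        )


# ---------------------------------------------------------------------------
# rotations


def _rx(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _ry(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


def _rz(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def rotation_from_euler(angles: EulerAngles | np.ndarray) -> np.ndarray:
    """Rotation matrix ``Rx(tx) @ Ry(ty) @ Rz(tz)`` (intrinsic x->y->z)."""
    if isinstance(angles, EulerAngles):
        tx, ty, tz = angles.tx, angles.ty, angles.tz
    else:
        tx, ty, tz = np.asarray(angles, dtype=float).reshape(3)
    return _rx(tx) @ _ry(ty) @ _rz(tz)


def euler_from_rotation(R: np.ndarray, *, strict: bool = True) -> EulerAngles:
    """Recover intrinsic x->y->z Euler angles from a rotation matrix.

    At gimbal lock (|ty| = pi/2) the x and z rotations are not separable;
    the tie is broken by setting tz = 0 and absorbing the remainder into tx.
    """
    R = _check_rotation(R) if strict else np.asarray(R, dtype=float)
    # R = Rx Ry Rz  =>  R[0,2] = sin(ty)
    sy = float(np.clip(R[0, 2], -1.0, 1.0))
    ty = float(np.arcsin(sy))
    if abs(sy) < 1.0 - 1e-10:
        tx = float(np.arctan2(-R[1, 2], R[2, 2]))
        tz = float(np.arctan2(-R[0, 1], R[0, 0]))
    else:  # gimbal lock: only tx ± tz determined
        tz = 0.0
        tx = float(np.arctan2(R[2, 1], R[1, 1]))
    return EulerAngles(tx, ty, tz)


def svd_project(M: np.ndarray) -> np.ndarray:
    """Project a 3x3 matrix onto the rotation group (nearest in Frobenius norm).

    The sign of the least-significant singular direction is flipped when
    needed so the result always has determinant +1.
    """
    M = np.asarray(M, dtype=float).reshape(3, 3)
    if not np.isfinite(M).all():
        raise ValueError("matrix contains non-finite values")
    U, s, Vt = np.linalg.svd(M)
    if s[1] < 1e-12 * max(s[0], 1.0):
        raise DegenerateGeometryError(
            "matrix is (nearly) rank-deficient; nearest rotation is not unique"
        )
    D = np.eye(3)
    if np.linalg.det(U @ Vt) < 0:
        D[2, 2] = -1.0
    return U @ D @ Vt


def rotation_angle(R: np.ndarray) -> float:
    """Geodesic rotation angle (radians) of a rotation matrix."""
    c = (np.trace(np.asarray(R, dtype=float)) - 1.0) / 2.0
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def apply_transform(cloud: PointCloud, t: RigidTransform, *, strict: bool = False) -> PointCloud:
    """Apply a rigid transform to a cloud's positions; features untouched."""
    if strict:
        _check_rotation(t.rotation)
    return replace(cloud, positions=t.apply_points(cloud.positions))


# ---------------------------------------------------------------------------
# canonical pose


def canonicalize_pose(
    landmarks: LandmarkSet,
    *,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> RigidTransform:
    """Rigid transform taking the landmarks into the canonical pelvic pose.

    The construction is: translate the PSIS midpoint to the origin, rotate
    about y so the PSIS segment is horizontal (zero depth difference), then
    rotate about x so L4 has zero depth.  Because the x-rotation can reintroduce
    a small PSIS depth difference when the PSIS segment is not level, the two
    angles are solved jointly by a short fixed-point iteration; the returned
    rotation is still exactly of the form ``Rx(beta) @ Ry(alpha)``.
    """
    for name in ("PSIS_L", "PSIS_R", "L4"):
        if name not in landmarks:
            raise MissingLandmarkError(name)
    psis_l, psis_r, l4 = landmarks["PSIS_L"], landmarks["PSIS_R"], landmarks["L4"]
    mid = 0.5 * (psis_l + psis_r)
    d = psis_r - psis_l  # left -> right PSIS segment
    v4 = l4 - mid
    scale = max(np.linalg.norm(d), 1.0)
    if np.linalg.norm(d) < 1e-9:
        raise DegenerateGeometryError("PSIS_L and PSIS_R coincide")
    if np.hypot(d[0], d[2]) < 1e-9 * scale:
        raise DegenerateGeometryError("PSIS segment is vertical; y-rotation undetermined")

    alpha = 0.0
    beta = 0.0
    for _ in range(max_iter):
        # alpha step: zero the depth (z) of Rx(beta) @ Ry(alpha) @ d.
        #   z-component = sin(beta) * d_y + cos(beta) * (-sin(alpha) d_x + cos(alpha) d_z)
        cb, sb = np.cos(beta), np.sin(beta)
        if abs(cb) < 1e-12:
            raise DegenerateGeometryError("canonical pose solve degenerate (beta at 90 deg)")
        c = -np.tan(beta) * d[1]
        a_coef, b_coef = -d[0], d[2]  # a sin(alpha) + b cos(alpha) = c
        r = np.hypot(a_coef, b_coef)
        phi = np.arctan2(b_coef, a_coef)
        val = np.clip(c / r, -1.0, 1.0)
        cand = [np.arcsin(val) - phi, np.pi - np.arcsin(val) - phi]
        # pick the branch that puts PSIS_R on the +x side (right = +x)
        def x_after(al):
            return np.cos(al) * d[0] + np.sin(al) * d[2]

        alpha = max(cand, key=x_after)
        # beta step: zero the depth of Rx(beta) @ Ry(alpha) @ v4
        u = _ry(alpha) @ v4
        if np.hypot(u[1], u[2]) < 1e-9 * scale:
            raise DegenerateGeometryError("L4 lies on the PSIS axis; x-rotation undetermined")
        beta = float(np.arctan2(-u[2], u[1]))
        R = _rx(beta) @ _ry(alpha)
        if abs((R @ d)[2]) < tol * scale and abs((R @ v4)[2]) < tol * scale:
            break
    else:
        raise DegenerateGeometryError(
            "canonical-pose solve did not converge; the landmark configuration "
            "is too far from an upright pelvis for a y-then-x rotation"
        )
    R = _rx(float(beta)) @ _ry(float(alpha))
    return RigidTransform(R, -R @ mid)
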