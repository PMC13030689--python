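"""Readers/writers for the exchange formats the pipeline consumes.

Point clouds: PLY (ascii and binary little-endian, vertices only, with an
optional integer ``label`` scalar property), OBJ (vertex records only) and
whitespace-separated XYZ text.  Landmarks: CSV with columns name,x,y,z in
mm.  Labels can also travel as a one-integer-per-line sidecar file.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .geometry import LandmarkSet, PointCloud
from .preprocessing import LabelVector

__all__ = [
    "read_point_cloud",
    "write_point_cloud",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "read_labels",
    "write_labels",
]


def _read_ply_ascii_with_labels(path: Path):
    """Minimal ascii-PLY vertex parser that understands a label property.

    Returns None for binary PLY (delegated to trimesh).
    """
    try:
        return _parse_ascii_ply(path)
    except UnicodeDecodeError:
        return None


def _parse_ascii_ply(path: Path):
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise ValueError(f"{path} is not a PLY file")
        n_vertex, props = 0, []
        while True:
            line = fh.readline()
            if not line:
                raise ValueError("unterminated PLY header")
            tok = line.split()
            if not tok:
                continue
            if tok[0] == "format" and tok[1] != "ascii":
                return None  # binary: delegate to trimesh
            if tok[0] == "element" and tok[1] == "vertex":
                n_vertex = int(tok[2])
            elif tok[0] == "property" and n_vertex:
                props.append(tok[-1])
            elif tok[0] == "end_header":
                break
        data = np.loadtxt(fh, max_rows=n_vertex, ndmin=2)
    cols = {p: data[:, i] for i, p in enumerate(props)}
    pts = np.stack([cols["x"], cols["y"], cols["z"]], axis=1)
    labels = cols.get("label")
    return pts, (None if labels is None else labels.astype(np.int64))


def read_point_cloud(path: str | Path) -> tuple[PointCloud, LabelVector | None]:
    """Read PLY/OBJ/XYZ into a PointCloud (+ labels when a PLY carries them)."""
    path = Path(path)
    suffix = path.suffix.lower()
    labels = None
    if suffix == ".ply":
        parsed = _read_ply_ascii_with_labels(path)
        if parsed is not None:
            pts, raw_labels = parsed
            if raw_labels is not None:
                labels = LabelVector(
                    raw_labels, int(raw_labels.max()) + 1 if raw_labels.size else 2
                )
        else:
            mesh = trimesh.load(path, process=False)
            pts = np.asarray(mesh.vertices, dtype=float)
    elif suffix == ".obj":
        mesh = trimesh.load(path, process=False)
        pts = np.asarray(mesh.vertices, dtype=float)
    elif suffix in (".xyz", ".txt"):
        pts = np.loadtxt(path, ndmin=2)[:, :3]
    else:
        raise ValueError(f"unsupported point-cloud format {suffix!r}")
    return PointCloud(pts), labels


def write_point_cloud(
    cloud: PointCloud,
    path: str | Path,
    labels: LabelVector | None = None,
    binary: bool = False,
) -> None:
    """Write PLY (ascii by default; binary via trimesh), OBJ or XYZ."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    suffix = path.suffix.lower()
    pts = cloud.positions
    if suffix == ".ply":
        if binary:
            if labels is not None:
                raise ValueError("labels are only supported in ascii PLY output")
            trimesh.PointCloud(pts).export(path, file_type="ply")
            return
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {len(pts)}\n")
            fh.write("property float x\nproperty float y\nproperty float z\n")
            if labels is not None:
                fh.write("property int label\n")
            fh.write("end_header\n")
            if labels is not None:
                for p, l in zip(pts, labels.labels):
                    fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {int(l)}\n")
            else:
                for p in pts:
                    fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
    elif suffix == ".obj":
        with open(path, "w") as fh:
            for p in pts:
                fh.write(f"v {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
    elif suffix in (".xyz", ".txt"):
        np.savetxt(path, pts, fmt="%.6f")
    else:
        raise ValueError(f"unsupported point-cloud format {suffix!r}")


def read_landmarks_csv(path: str | Path) -> LandmarkSet:
    df = pd.read_csv(path)
    required = {"name", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"landmark CSV must have columns {sorted(required)}")
    return LandmarkSet({r["name"]: (r.x, r.y, r.z) for _, r in df.iterrows()})


def write_landmarks_csv(landmarks: LandmarkSet, path: str | Path, frame: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {"name": n, "x": v[0], "y": v[1], "z": v[2]} for n, v in landmarks.items()
    ]
    df = pd.DataFrame(rows, columns=["name", "x", "y", "z"])
    if frame is not None:
        df["frame"] = frame
    df.to_csv(path, index=False)


def read_labels(path: str | Path, n_classes: int | None = None) -> LabelVector:
    vals = np.loadtxt(path, dtype=np.int64, ndmin=1)
    return LabelVector(vals, n_classes or int(vals.max()) + 1)


def write_labels(labels: LabelVector, path: str | Path) -> None:
    np.savetxt(path, labels.labels, fmt="%d")
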