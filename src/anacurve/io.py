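"""Readers and writers for surface point clouds, landmarks and curves.

Point clouds travel as PLY (binary or ASCII, via trimesh) or OBJ vertices;
landmarks and curves as plain CSV (columns name/curve_id, x_mm, y_mm, z_mm)
or JSON.  Only vertex data are used -- the algorithms operate on point sets,
not mesh connectivity.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .frames import LandmarkSet, SurfacePointCloud

__all__ = [
    "read_point_cloud", "write_point_cloud",
    "read_landmarks", "write_landmarks",
    "read_curves", "write_curves",
]


def read_point_cloud(path) -> SurfacePointCloud:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such surface file: {path}")
    if path.suffix.lower() == ".obj":
        verts = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("v "):
                    verts.append([float(v) for v in line.split()[1:4]])
        if not verts:
            raise ValueError(f"no vertices found in {path}")
        return SurfacePointCloud(np.asarray(verts))
    import trimesh

    obj = trimesh.load(str(path), process=False)
    if hasattr(obj, "vertices"):
        pts = np.asarray(obj.vertices, dtype=float)
    else:
        pts = np.asarray(obj.geometry[next(iter(obj.geometry))].vertices, dtype=float)
    colors = None
    visual = getattr(obj, "visual", None)
    if visual is not None and getattr(visual, "vertex_colors", None) is not None:
        vc = np.asarray(visual.vertex_colors)
        if len(vc) == len(pts):
            colors = vc
    return SurfacePointCloud(pts, colors)


def write_point_cloud(cloud: SurfacePointCloud, path, ascii_ply: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".obj":
        with open(path, "w") as fh:
            for p in cloud.points:
                fh.write(f"v {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        return path
    import trimesh

    pc = trimesh.PointCloud(cloud.points)
    data = pc.export(file_type="ply", encoding="ascii" if ascii_ply else "binary")
    mode = "w" if isinstance(data, str) else "wb"
    with open(path, mode) as fh:
        fh.write(data)
    return path


def read_landmarks(path) -> LandmarkSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such landmark file: {path}")
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        names = list(data)
        pts = np.asarray([data[n] for n in names], dtype=float)
        return LandmarkSet(names, pts)
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    name_col = cols.get("name", df.columns[0])
    xyz = [cols.get(k, k) for k in ("x_mm", "y_mm", "z_mm")]
    if not all(c in df.columns for c in xyz):
        xyz = [cols[k] for k in ("x", "y", "z")]
    return LandmarkSet(df[name_col].astype(str).tolist(), df[xyz].to_numpy(float))


def write_landmarks(landmarks: LandmarkSet, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(
            {n: p.tolist() for n, p in landmarks.as_dict().items()}, indent=1))
        return path
    pd.DataFrame({
        "name": landmarks.names,
        "x_mm": landmarks.points[:, 0],
        "y_mm": landmarks.points[:, 1],
        "z_mm": landmarks.points[:, 2],
    }).to_csv(path, index=False)
    return path


def write_curves(curves: dict[str, np.ndarray], path) -> Path:
    """Write named 3-D polylines as CSV (curve_id, x_mm, y_mm, z_mm)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = []
    for cid, pts in curves.items():
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        frames.append(pd.DataFrame({
            "curve_id": cid, "x_mm": pts[:, 0], "y_mm": pts[:, 1], "z_mm": pts[:, 2]}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_curves(path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    return {str(cid): g[["x_mm", "y_mm", "z_mm"]].to_numpy(float)
            for cid, g in df.groupby("curve_id", sort=False)}
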