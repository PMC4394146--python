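"""Surface point clouds, local PCA frames and planar transect strips.

An anatomical surface is an unstructured set of 3-D points in mm.  Navigation
works through local orthogonal frames: the first two principal components of
a neighbourhood span the tangent plane (n1, n2) and the third lies along the
surface normal (n3).  A transect strip is the set of points within a thin
planar slab |p' n2| <= delta (optionally restricted to the half-plane
p' n1 > 0, for radial transects), reduced to in-plane coordinates with the
projection on n1 as abscissa and the projection on n3 (depth) as ordinate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["SurfacePointCloud", "LandmarkSet", "LocalFrame", "TransectStrip",
           "local_frame", "planar_strip", "rotate_frame"]

TORSO_LANDMARKS = ("prom", "med", "lat", "inf", "ssn", "xipho")
LIP_LANDMARKS = ("ch_l", "ch_r", "cphl_l", "cphl_r", "ls", "li", "sto")


@dataclass
class SurfacePointCloud:
    """Unstructured 3-D surface points (mm), optional per-point colour."""

    points: np.ndarray
    colors: np.ndarray | None = None
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if len(self.points) < 3:
            raise ValueError("a surface needs at least 3 points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points contain non-finite coordinates")

    def __len__(self):
        return len(self.points)

    @property
    def tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.points)
        return self._tree

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def mean_spacing(self, sample: int = 2000) -> float:
        """Mean nearest-neighbour distance, from a deterministic subsample."""
        idx = np.linspace(0, len(self) - 1, min(sample, len(self))).astype(int)
        d, _ = self.tree.query(self.points[idx], k=2)
        return float(d[:, 1].mean())


@dataclass
class LandmarkSet:
    """Named 3-D landmark points (mm)."""

    names: list[str]
    points: np.ndarray

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if len(self.names) != len(self.points):
            raise ValueError("names and points disagree in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("landmark names must be unique")

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.points[self.names.index(name)]
        except ValueError:
            raise KeyError(f"landmark '{name}' not present") from None

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def require(self, *names: str) -> None:
        for nm in names:
            if nm not in self.names:
                raise KeyError(f"required landmark '{nm}' is missing")

    def as_dict(self) -> dict[str, np.ndarray]:
        return dict(zip(self.names, self.points))


@dataclass(frozen=True)
class LocalFrame:
    """Origin plus right-handed orthonormal axes (n1, n2, n3)."""

    origin: np.ndarray
    n1: np.ndarray
    n2: np.ndarray
    n3: np.ndarray

    def __post_init__(self):
        for name in ("origin", "n1", "n2", "n3"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("axes are not orthonormal")

    @property
    def rotation(self) -> np.ndarray:
        return np.vstack([self.n1, self.n2, self.n3])

    def to_local(self, points: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(points) - self.origin) @ self.rotation.T

    def to_world(self, local: np.ndarray) -> np.ndarray:
        return np.atleast_2d(local) @ self.rotation + self.origin


@dataclass
class TransectStrip:
    """Points of a planar slab with in-plane coordinates.

    ``abscissa`` is the projection on n1 (along the transect), ``ordinate``
    the projection on n3 (depth), both relative to the frame origin.
    """

    points: np.ndarray
    frame: LocalFrame
    abscissa: np.ndarray
    ordinate: np.ndarray
    delta: float
    half: bool = False

    def __len__(self):
        return len(self.points)

    @property
    def plane_coords(self) -> np.ndarray:
        return np.column_stack([self.abscissa, self.ordinate])

    def to_world(self, abscissa, ordinate) -> np.ndarray:
        """Map in-plane coordinates back to 3-D points on the strip plane."""
        a = np.atleast_1d(np.asarray(abscissa, dtype=float))
        o = np.atleast_1d(np.asarray(ordinate, dtype=float))
        return self.frame.origin + a[:, None] * self.frame.n1 + o[:, None] * self.frame.n3


def _orient(v: np.ndarray, reference: np.ndarray) -> np.ndarray:
    return -v if float(v @ reference) < 0 else v


def local_frame(cloud: SurfacePointCloud, center, radius: float = 12.0,
                reference_direction=None, min_neighbors: int = 10) -> LocalFrame:
    """Local PCA frame at ``center`` from the neighbourhood within ``radius`` mm.

    n3 is the smallest-variance direction, oriented outward (away from the
    cloud centroid); n1 is the first principal direction, oriented toward
    ``reference_direction`` when given; n2 completes a right-handed triad.
    """
    center = np.asarray(center, dtype=float)
    idx = cloud.tree.query_ball_point(center, radius)
    if len(idx) < min_neighbors:
        raise ValueError(
            f"only {len(idx)} neighbours within {radius} mm of {center}; "
            f"need at least {min_neighbors}")
    nb = cloud.points[idx]
    centred = nb - nb.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    n1, _, n3 = vt
    n3 = _orient(n3, center - cloud.centroid)
    if reference_direction is not None:
        ref = np.asarray(reference_direction, dtype=float)
        ref = ref - (ref @ n3) * n3
        if np.linalg.norm(ref) > 1e-12:
            n1 = _orient(n1, ref)
    n2 = np.cross(n3, n1)
    return LocalFrame(center, n1, n2, n3)


def planar_strip(cloud: SurfacePointCloud, frame: LocalFrame, delta: float = 1.0,
                 half: bool = False) -> TransectStrip:
    """Extract the slab |p' n2| <= delta (and p' n1 > 0 if ``half``)."""
    if delta < 0:
        raise ValueError("delta must be non-negative")
    local = frame.to_local(cloud.points)
    mask = np.abs(local[:, 1]) <= delta
    if half:
        mask &= local[:, 0] > 0
    if not np.any(mask):
        warnings.warn("planar_strip: no points satisfy the slab condition",
                      stacklevel=2)
    return TransectStrip(cloud.points[mask], frame, local[mask, 0], local[mask, 2],
                         float(delta), half)


def rotate_frame(frame: LocalFrame, angle: float) -> LocalFrame:
    """Rotate n1, n2 about n3 by ``angle`` (radians, right-hand rule)."""
    c, s = np.cos(angle), np.sin(angle)
    n1 = c * frame.n1 + s * frame.n2
    n2 = -s * frame.n1 + c * frame.n2
    return LocalFrame(frame.origin, n1, n2, frame.n3)
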