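"""Semi-landmark grids over bounded anatomical surfaces.

Once a boundary curve is known, the enclosed surface is regularised into a
grid of semi-landmarks -- surface points placed by geometric construction at
positions that correspond across specimens.  For a breast, points are placed
along each radial transect at fixed proportional arc lengths between the
apex (prom) and the boundary; because all transects converge at the apex,
the proportions follow normalised exponential quantiles so that spacing is
sparse near the apex and tightens toward the boundary, giving a more even
coverage of the surface.  For lips, points equally spaced on the two
bounding curves of each lip are joined by principal curves across the lip
surface, carrying a number of points that grows with the local lip width.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .breast import BoundaryCurve3D
from .frames import SurfacePointCloud, TransectStrip
from .lips import LipCurves
from .principal_curve import PrincipalCurve, fit_principal_curve, project_to_curve

__all__ = ["SemiLandmarkGrid", "exponential_spacings", "breast_semilandmarks",
           "lip_semilandmarks", "triangulate"]


@dataclass
class SemiLandmarkGrid:
    """Ordered semi-landmarks with (transect index, within-transect index)
    labels and a descriptor guaranteeing cross-specimen correspondence."""

    points: np.ndarray
    labels: np.ndarray          # (n, 2) int: (transect index, point index)
    descriptor: dict

    def __len__(self):
        return len(self.points)

    def to_frame(self, specimen_id: str = ""):
        import pandas as pd

        df = pd.DataFrame({
            "transect_idx": self.labels[:, 0],
            "point_idx": self.labels[:, 1],
            "x": self.points[:, 0], "y": self.points[:, 1], "z": self.points[:, 2],
        })
        if specimen_id:
            df.insert(0, "specimen_id", specimen_id)
        return df


def exponential_spacings(r: int, p_max: float = 0.99) -> np.ndarray:
    """Normalised exponential quantiles tau_i = q(i*p_max/r) / q(p_max).

    Strictly increasing in (0, 1] with tau_r = 1; successive increments grow
    with i, so when the sequence is laid out as proportions of arc length the
    gaps shrink in one direction and widen in the other.
    """
    if r < 2:
        raise ValueError(f"need at least r=2 points, got {r}")
    if not 0 < p_max < 1:
        raise ValueError("p_max must be in (0, 1)")
    i = np.arange(1, r + 1)
    q = stats.expon.ppf(i * p_max / r)
    return q / q[-1]


def _apex_proportions(r: int, p_max: float = 0.99) -> np.ndarray:
    """Proportional distances from the apex: sparse at the apex (where the
    transects converge), dense toward the boundary, last point exactly on it."""
    tau = exponential_spacings(r, p_max)
    return 1.0 - np.concatenate([tau[:-1][::-1], [0.0]])


def breast_semilandmarks(transect_curves: list[PrincipalCurve],
                         boundary: BoundaryCurve3D,
                         apex: np.ndarray, r: int = 20,
                         p_max: float = 0.99) -> SemiLandmarkGrid:
    """Apex plus k*r semi-landmarks over the breast surface.

    Each transect principal curve (running from the apex outward) is
    truncated at its crossing of the boundary curve; r points are placed at
    the apex-proportional distances and the grid is ordered apex first, then
    transect-major.
    """
    k = len(transect_curves)
    if k != len(boundary.points):
        raise ValueError("one transect curve per boundary point is required")
    props = _apex_proportions(r, p_max)
    pts = [np.asarray(apex, dtype=float)]
    labels = [(-1, 0)]
    for i, curve in enumerate(transect_curves):
        s_bound, dist, _ = project_to_curve(curve, boundary.points[i])
        if s_bound <= 0:
            raise ValueError(f"transect {i} does not reach the boundary")
        s_vals = props * s_bound
        on_curve = curve(s_vals)
        on_curve[-1] = boundary.points[i]  # tau_r = 1 sits exactly on the boundary
        for j in range(r):
            pts.append(on_curve[j])
            labels.append((i, j))
    descriptor = {"kind": "breast", "k": k, "r": r, "p_max": p_max}
    return SemiLandmarkGrid(np.asarray(pts), np.asarray(labels, dtype=int), descriptor)


def breast_grid(result, landmarks, r: int = 20, df: float = 6.0,
                p_max: float = 0.99) -> SemiLandmarkGrid:
    """Semi-landmark grid straight from a breast-pipeline result.

    Refits each radial strip as a 3-D principal curve (initialised by the
    in-plane abscissa) and places the apex-plus-k*r grid bounded by the
    fitted boundary curve.
    """
    curves = []
    for i, strip in enumerate(result.strips):
        if len(strip) < df + 2:
            raise ValueError(f"transect {i} has too few points for the grid")
        curves.append(fit_principal_curve(strip.points, df=df,
                                          initial_index=strip.abscissa))
    return breast_semilandmarks(curves, result.boundary, landmarks["prom"],
                                r=r, p_max=p_max)


def _resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(t, s, points[:, j]) for j in range(points.shape[1])])


def _pair_counts(widths: np.ndarray, lo: int = 3, hi: int = 24) -> np.ndarray:
    """Points per cross-transect: ramp with lip width from ``lo`` at the
    corners to ``hi`` at the widest pair."""
    wmax = widths.max()
    if wmax <= 0:
        raise ValueError("degenerate lip: zero width everywhere")
    return np.maximum(lo, np.rint(hi * widths / wmax).astype(int))


def lip_semilandmarks(curves: LipCurves, cloud: SurfacePointCloud | None = None,
                      n_boundary: int = 50, cross_df: float = 4.0,
                      strip_tol: float = 1.5) -> SemiLandmarkGrid:
    """Semi-landmarks for the two lips bounded by the fitted curves.

    For each lip the outer boundary curve and the midline each carry
    ``n_boundary`` points equally spaced in arc length; corresponding pairs
    are joined across the lip surface.  When a point cloud is given, the
    joining transects are principal curves through the strip of surface
    points around each pair; otherwise straight chords are used.  Per-pair
    counts ramp from 3 near the corners to 24 at the widest point, so the
    total is a deterministic function of the descriptor.
    """
    pts, labels = [], []
    tidx = 0
    counts_record = []
    for lip, outer in (("upper", curves.upper), ("lower", curves.lower)):
        a = _resample_polyline(outer, n_boundary)
        b = _resample_polyline(curves.midline, n_boundary)
        widths = np.linalg.norm(a - b, axis=1)
        counts = _pair_counts(widths)
        counts_record.append(counts)
        for i in range(n_boundary):
            m = counts[i]
            if cloud is not None and m > 2 and widths[i] > strip_tol:
                chord = b[i] - a[i]
                L = np.linalg.norm(chord)
                u = chord / L
                rel = cloud.points - a[i]
                t = rel @ u
                perp = np.linalg.norm(rel - np.outer(t, u), axis=1)
                sel = (t > -1.0) & (t < L + 1.0) & (perp < strip_tol)
                cross_pts = None
                if sel.sum() >= max(8, int(cross_df) + 2):
                    try:
                        pc = fit_principal_curve(cloud.points[sel],
                                                 df=min(cross_df, sel.sum() - 2),
                                                 initial_index=t[sel])
                        sa = project_to_curve(pc, a[i])[0]
                        sb = project_to_curve(pc, b[i])[0]
                        svals = np.linspace(sa, sb, m)
                        cross_pts = pc(svals)
                        cross_pts[0], cross_pts[-1] = a[i], b[i]
                    except ValueError:
                        cross_pts = None
                if cross_pts is None:
                    cross_pts = np.linspace(0, 1, m)[:, None] * (b[i] - a[i]) + a[i]
            else:
                cross_pts = np.linspace(0, 1, m)[:, None] * (b[i] - a[i]) + a[i]
            for j in range(m):
                pts.append(cross_pts[j])
                labels.append((tidx, j))
            tidx += 1
    descriptor = {"kind": "lip", "n_boundary": n_boundary,
                  "counts": [c.tolist() for c in counts_record]}
    return SemiLandmarkGrid(np.asarray(pts), np.asarray(labels, dtype=int), descriptor)


def triangulate(grid: SemiLandmarkGrid) -> np.ndarray:
    """Triangle faces (indices into ``grid.points``) over the grid.

    Breast grids get an apex fan plus two triangles per quad between
    adjacent transects (wrapping around); ragged lip grids are stitched
    between adjacent cross-transects by a greedy parameter march.  Faces
    with duplicated vertices are dropped with a warning.
    """
    import warnings

    labels = grid.labels
    faces = []
    if grid.descriptor.get("kind") == "breast":
        k, r = grid.descriptor["k"], grid.descriptor["r"]
        idx = {(int(t), int(j)): n for n, (t, j) in enumerate(labels)}
        apex = 0
        for t in range(k):
            t2 = (t + 1) % k
            faces.append([apex, idx[(t, 0)], idx[(t2, 0)]])
            for j in range(r - 1):
                a, b = idx[(t, j)], idx[(t, j + 1)]
                c, d = idx[(t2, j)], idx[(t2, j + 1)]
                faces.append([a, b, d])
                faces.append([a, d, c])
    else:
        rows = []
        for t in range(labels[:, 0].max() + 1):
            rows.append(np.nonzero(labels[:, 0] == t)[0])
        half = len(rows) // 2
        for block in (rows[:half], rows[half:]):
            for ra, rb in zip(block[:-1], block[1:]):
                ia = ib = 0
                while ia < len(ra) - 1 or ib < len(rb) - 1:
                    fa = (ia + 1) / max(len(ra) - 1, 1)
                    fb = (ib + 1) / max(len(rb) - 1, 1)
                    if ib >= len(rb) - 1 or (ia < len(ra) - 1 and fa <= fb):
                        faces.append([ra[ia], ra[ia + 1], rb[ib]])
                        ia += 1
                    else:
                        faces.append([ra[ia], rb[ib + 1], rb[ib]])
                        ib += 1
    faces = np.asarray(faces, dtype=int)
    ok = (faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2]) & (faces[:, 0] != faces[:, 2])
    # drop faces with (near-)duplicate vertex positions
    p = grid.points
    area2 = np.linalg.norm(np.cross(p[faces[:, 1]] - p[faces[:, 0]],
                                    p[faces[:, 2]] - p[faces[:, 0]]), axis=1)
    degen = area2 < 1e-12
    if np.any(~ok | degen):
        warnings.warn(f"dropping {int((~ok | degen).sum())} degenerate faces")
    return faces[ok & ~degen]
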