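"""End-to-end breast boundary estimation.

Radial transect strips fan out from the most prominent point (prom) of the
breast; each strip's principal curve yields candidate boundary points at
local maxima of positive curvature (the crease where the mound joins the
chest wall).  Candidates are screened against the manually supplied
landmarks (distance from prom, protrusion band, elevation band), gaps are
interpolated from side curves, and a closed 3-D boundary curve is fitted
through the retained points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curvature import local_curvature_maxima, planar_curvature
from .frames import (LandmarkSet, LocalFrame, SurfacePointCloud, TransectStrip,
                     local_frame, planar_strip, rotate_frame)
from .principal_curve import fit_principal_curve
from .pspline import fit_pspline

__all__ = ["RadialCandidate", "BoundaryCurve3D", "BreastConfig",
           "radial_transects", "candidate_boundary_points", "filter_candidates",
           "interpolate_gaps", "fit_boundary", "estimate_breast_boundary"]


@dataclass
class BreastConfig:
    n_transects: int = 51
    delta: float = 1.0                 # slab half-thickness, mm
    neighborhood_radius: float = 12.0  # local-frame neighbourhood at prom, mm
    transect_df: float = 6.0
    boundary_df: float = 12.0
    proportion: float = 0.7            # exclusion rule (a) proportion
    tolerance: float = 10.0            # exclusion rules (b)/(c) tolerance, mm
    length_multiple: float = 1.5       # transect stopping multiple
    min_strip_points: int = 12


@dataclass
class RadialCandidate:
    transect: int
    angle: float
    point: np.ndarray          # 3-D location, mm
    arc_length: float          # along the transect principal curve
    curvature: float
    retained: bool = True
    excluded_by: str | None = None


@dataclass
class BoundaryCurve3D:
    """Closed boundary estimate with per-transect support points."""

    angles: np.ndarray
    points: np.ndarray             # fitted boundary at each transect angle
    interpolated: np.ndarray       # bool flag per transect
    curve_angles: np.ndarray       # dense angle grid
    curve_points: np.ndarray       # dense fitted curve
    closed: bool = True

    @property
    def closure_gap(self) -> float:
        return float(np.linalg.norm(self.curve_points[0] - self.curve_points[-1]))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "transect_index": np.arange(len(self.angles)),
            "angle": self.angles,
            "x": self.points[:, 0], "y": self.points[:, 1], "z": self.points[:, 2],
            "interpolated_flag": self.interpolated.astype(int),
        })


def _midline_plane(cloud: SurfacePointCloud, landmarks: LandmarkSet):
    """Plane through ssn and xipho, approximately orthogonal to the surface.

    Returns (origin, normal) with the normal oriented away from prom's side,
    so ``(p - origin) @ normal > 0`` flags points beyond the midline.
    """
    landmarks.require("prom", "ssn", "xipho")
    ssn, xipho, prom = landmarks["ssn"], landmarks["xipho"], landmarks["prom"]
    m = ssn - xipho
    n_ssn = _surface_normal(cloud, ssn)
    n_xipho = _surface_normal(cloud, xipho)
    n_avg = n_ssn + n_xipho
    n_avg /= np.linalg.norm(n_avg)
    normal = np.cross(m / np.linalg.norm(m), n_avg)
    normal /= np.linalg.norm(normal)
    if (prom - xipho) @ normal > 0:
        normal = -normal
    return xipho, normal


def _surface_normal(cloud: SurfacePointCloud, point, radius: float = 12.0):
    fr = local_frame(cloud, point, radius)
    return fr.n3


def radial_transects(cloud: SurfacePointCloud, landmarks: LandmarkSet,
                     config: BreastConfig | None = None) -> list[TransectStrip]:
    """Radial half-strips from prom, clipped by the midline plane and by the
    running length rule.

    The frame at prom takes n1 toward the lateral landmark; successive
    transects rotate clockwise (viewed along -n3) in equal steps.  Each strip
    stops at the ssn--xipho midline plane; once two previous transects have
    produced boundary candidates, the strip is also clipped to
    ``length_multiple`` times the largest recent candidate arc length (the
    clip is applied here through a per-strip cache filled by
    :func:`candidate_boundary_points` when running the full pipeline).
    """
    config = config or BreastConfig()
    if config.n_transects < 8:
        raise ValueError("need at least 8 radial transects")
    landmarks.require("prom", "ssn", "xipho", "lat")
    prom = landmarks["prom"]
    frame0 = local_frame(cloud, prom, config.neighborhood_radius,
                         reference_direction=landmarks["lat"] - prom)
    origin_mid, normal_mid = _midline_plane(cloud, landmarks)
    strips = []
    for i in range(config.n_transects):
        # clockwise when viewed along -n3
        frame = rotate_frame(frame0, -2 * np.pi * i / config.n_transects)
        strip = planar_strip(cloud, frame, config.delta, half=True)
        keep = (strip.points - origin_mid) @ normal_mid <= 0
        strips.append(TransectStrip(strip.points[keep], frame,
                                    strip.abscissa[keep], strip.ordinate[keep],
                                    strip.delta, True))
    return strips


def candidate_boundary_points(strips: list[TransectStrip],
                              config: BreastConfig | None = None,
                              length_rule: bool = True) -> list[list[RadialCandidate]]:
    """Per-strip boundary candidates: positive local curvature maxima of the
    transect principal curve.

    With ``length_rule`` the strip data are clipped to ``length_multiple``
    times the largest candidate arc length of the two previous transects
    before fitting, mirroring the sequential construction.
    """
    config = config or BreastConfig()
    if not strips:
        raise ValueError("no strips supplied")
    out: list[list[RadialCandidate]] = []
    recent: list[float] = []
    for i, strip in enumerate(strips):
        angle = 2 * np.pi * i / len(strips)
        abscissa, ordinate, pts = strip.abscissa, strip.ordinate, strip.points
        if len(abscissa) < max(config.min_strip_points, int(config.transect_df) + 2):
            out.append([])
            continue
        plane = np.column_stack([abscissa, ordinate])
        curve = fit_principal_curve(plane, df=config.transect_df,
                                    initial_index=abscissa)
        if length_rule and len(recent) >= 2:
            # stop the transect at length_multiple times the largest recent
            # candidate arc distance, then refit on the clipped points
            cap = config.length_multiple * max(recent[-2:])
            if curve.smax > cap:
                keep = curve.s_data <= cap
                if keep.sum() >= max(config.min_strip_points,
                                     int(config.transect_df) + 2):
                    abscissa, ordinate, pts = abscissa[keep], ordinate[keep], pts[keep]
                    plane = plane[keep]
                    curve = fit_principal_curve(plane, df=config.transect_df,
                                                initial_index=abscissa)
        profile = planar_curvature(curve)
        maxima = local_curvature_maxima(profile, require_positive=True)
        cands = []
        for s, kappa in maxima:
            foot = curve(np.array([s]))[0]
            world = strip.to_world([foot[0]], [foot[1]])[0]
            cands.append(RadialCandidate(i, angle, world, float(s), float(kappa)))
        out.append(cands)
        if cands:
            recent.append(max(c.arc_length for c in cands))
    return out


def filter_candidates(candidates: list[list[RadialCandidate]],
                      cloud: SurfacePointCloud, landmarks: LandmarkSet,
                      config: BreastConfig | None = None) -> list[list[RadialCandidate]]:
    """Apply the landmark-based exclusion rules (a)-(c) in place.

    (a) not too close to prom: ||c - prom|| > proportion * min(||med - prom||,
        ||lat - prom||);
    (b) protrusion along n (mean of the surface normals at ssn and xipho)
        within [min(med'n, lat'n) - tol, max(med'n, lat'n) + tol];
    (c) elevation along m (unit vector from xipho to ssn) within
        (inf'm - tol, ssn'm).
    Projections use coordinates relative to the cloud centroid so the
    inequalities are origin-invariant.
    """
    config = config or BreastConfig()
    landmarks.require("prom", "med", "lat", "inf", "ssn", "xipho")
    prom, med, lat = landmarks["prom"], landmarks["med"], landmarks["lat"]
    inf_, ssn, xipho = landmarks["inf"], landmarks["ssn"], landmarks["xipho"]
    n = _surface_normal(cloud, ssn) + _surface_normal(cloud, xipho)
    n /= np.linalg.norm(n)
    m = ssn - xipho
    m /= np.linalg.norm(m)
    origin = cloud.centroid
    tol = config.tolerance

    def proj(p, v):
        return float((p - origin) @ v)

    dist_floor = config.proportion * min(np.linalg.norm(med - prom),
                                         np.linalg.norm(lat - prom))
    prot_lo = min(proj(med, n), proj(lat, n)) - tol
    prot_hi = max(proj(med, n), proj(lat, n)) + tol
    elev_lo = proj(inf_, m) - tol
    elev_hi = proj(ssn, m)
    for cands in candidates:
        for c in cands:
            if np.linalg.norm(c.point - prom) <= dist_floor:
                c.retained, c.excluded_by = False, "a"
            elif not (prot_lo <= proj(c.point, n) <= prot_hi):
                c.retained, c.excluded_by = False, "b"
            elif not (elev_lo < proj(c.point, m) < elev_hi):
                c.retained, c.excluded_by = False, "c"
    return candidates


def _best_per_transect(candidates: list[list[RadialCandidate]]):
    """Highest-curvature retained candidate per transect (None where absent)."""
    out = []
    for cands in candidates:
        retained = [c for c in cands if c.retained]
        out.append(max(retained, key=lambda c: c.curvature) if retained else None)
    return out


def _gap_runs(present: np.ndarray):
    """Maximal circular runs of missing transects as (start, length)."""
    k = len(present)
    if present.all():
        return []
    if not present.any():
        raise ValueError("no transect produced a retained boundary candidate")
    runs = []
    i = 0
    while i < k:
        if not present[i] and (present[(i - 1) % k] or k == 1):
            j = i
            length = 0
            while not present[j % k]:
                length += 1
                j += 1
            runs.append((i, length))
            i = j
        else:
            i += 1
    return runs


def _side_curve(angles: np.ndarray, points: np.ndarray, df: float):
    """Per-coordinate smooth of boundary points against transect angle,
    with linear extrapolation beyond the fitted angular range."""
    df_eff = min(df, max(2.0, len(angles) - 2.0))
    nb = max(int(df_eff) + 5, 8)
    models = [fit_pspline(angles, points[:, j], nbasis=nb, df=df_eff)
              for j in range(points.shape[1])]

    def predict(angle: float) -> np.ndarray:
        return np.array([m.predict_extrapolate([angle])[0] for m in models])

    return predict


def interpolate_gaps(per_transect: list, angles: np.ndarray,
                     config: BreastConfig | None = None,
                     side_window: int = 10):
    """Fill missing transect boundary points from extended side curves.

    For a gap of l transects, side curves are fitted to the retained points
    on each flank and extended; gap transect i (1-based from the left)
    receives the weighted average ((l+1-i)*bL_i + i*bR_i) / (l+1).

    Returns (points array (k, 3), interpolated mask).
    """
    config = config or BreastConfig()
    k = len(per_transect)
    present = np.array([p is not None for p in per_transect])
    if (~present).sum() > k // 2:
        raise ValueError("gaps span more than half the transects; boundary unidentifiable")
    pts = np.zeros((k, 3))
    for i, p in enumerate(per_transect):
        if p is not None:
            pts[i] = p.point if isinstance(p, RadialCandidate) else np.asarray(p)
    interp = np.zeros(k, dtype=bool)
    for start, length in _gap_runs(present):
        left_idx = [(start - 1 - j) % k for j in range(side_window)]
        left_idx = [ix for ix in left_idx if present[ix]]
        right_idx = [(start + length + j) % k for j in range(side_window)]
        right_idx = [ix for ix in right_idx if present[ix]]
        if len(left_idx) < 4 or len(right_idx) < 4:
            raise ValueError("too few retained candidates flanking a gap")
        # unwrap angles so each side is monotone around the gap
        gap_angles = np.array([angles[(start + j) % k] for j in range(length)])
        gap_unwrap = angles[start] + (2 * np.pi / k) * np.arange(length)
        la = angles[start] - (2 * np.pi / k) * np.arange(1, len(left_idx) + 1)
        ra = gap_unwrap[-1] + (2 * np.pi / k) * np.arange(1, len(right_idx) + 1)
        bL = _side_curve(la[::-1], pts[left_idx][::-1], config.boundary_df)
        bR = _side_curve(ra, pts[right_idx], config.boundary_df)
        for j in range(length):
            i_gap = (start + j) % k
            wl = (length - j) / (length + 1)
            wr = (j + 1) / (length + 1)
            pts[i_gap] = wl * bL(gap_unwrap[j]) + wr * bR(gap_unwrap[j])
            interp[i_gap] = True
    return pts, interp


def fit_boundary(points: np.ndarray, angles: np.ndarray,
                 config: BreastConfig | None = None) -> BoundaryCurve3D:
    """Closed 3-D boundary curve through per-transect points.

    The points are angle-ordered; the first and last 10% are duplicated with
    a +/- 2*pi shift before per-coordinate P-spline smoothing against angle,
    then the curve is evaluated on [0, 2*pi) -- a periodic continuation
    device that closes the boundary.
    """
    config = config or BreastConfig()
    points = np.asarray(points, dtype=float)
    angles = np.asarray(angles, dtype=float)
    if len(points) < 14:
        raise ValueError(f"need at least 14 boundary points, got {len(points)}")
    gaps = np.diff(np.sort(np.concatenate([angles, [angles.min() + 2 * np.pi]])))
    if gaps.max() > np.pi / 2:
        raise ValueError("angular coverage gap exceeds 90 degrees")
    order = np.argsort(angles)
    ang, pts = angles[order], points[order]
    pad = max(3, int(0.1 * len(ang)))
    ang_ext = np.concatenate([ang[-pad:] - 2 * np.pi, ang, ang[:pad] + 2 * np.pi])
    pts_ext = np.vstack([pts[-pad:], pts, pts[:pad]])
    models = [fit_pspline(ang_ext, pts_ext[:, j], nbasis=30, df=config.boundary_df)
              for j in range(3)]
    dense = np.linspace(0.0, 2 * np.pi, 721)
    curve = np.column_stack([m(dense) for m in models])
    at_transects = np.column_stack([m(ang) for m in models])
    out_pts = np.empty_like(points)
    out_pts[order] = at_transects
    return BoundaryCurve3D(angles, out_pts, np.zeros(len(angles), dtype=bool),
                           dense, curve)


@dataclass
class BreastBoundaryResult:
    boundary: BoundaryCurve3D
    candidates: list[list[RadialCandidate]]
    strips: list[TransectStrip]
    report: dict


def estimate_breast_boundary(cloud: SurfacePointCloud, landmarks: LandmarkSet,
                             config: BreastConfig | None = None) -> BreastBoundaryResult:
    """Full pipeline: transects -> candidates -> screening -> gaps -> boundary."""
    config = config or BreastConfig()
    strips = radial_transects(cloud, landmarks, config)
    candidates = candidate_boundary_points(strips, config)
    candidates = filter_candidates(candidates, cloud, landmarks, config)
    best = _best_per_transect(candidates)
    angles = np.array([2 * np.pi * i / len(strips) for i in range(len(strips))])
    pts, interp = interpolate_gaps(best, angles, config)
    boundary = fit_boundary(pts, angles, config)
    boundary.interpolated = interp
    n_cand = sum(len(c) for c in candidates)
    n_excl = {"a": 0, "b": 0, "c": 0}
    for cands in candidates:
        for c in cands:
            if c.excluded_by:
                n_excl[c.excluded_by] += 1
    report = {
        "n_transects": len(strips),
        "n_candidates": n_cand,
        "n_excluded": n_excl,
        "n_interpolated": int(interp.sum()),
        "closure_gap_mm": boundary.closure_gap,
    }
    return BreastBoundaryResult(boundary, candidates, strips, report)
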