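"""End-to-end lip boundary estimation.

Closed lips show three curves: the upper and lower boundary ridges and the
sharp valley where the lips meet.  Vertical strips across the mouth region
each yield a principal curve of depth against height; the valley crossing is
detected by the standardised derivative-difference statistic (a midline
point is declared only where |T| exceeds a threshold, so strips lateral to
the mouth contribute nothing), and ridge candidates are taken from local
maxima of ridge-sense curvature above and below the detected midline.
Corners of the mouth are located as the first and last strong curvature
maxima of the 3-D midline curve; the upper and lower boundaries are then
fitted with shape-penalised P-splines constrained to pass through the
corners exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .changepoint import TransectSignal, detect_feature, scan_derivative_change
from .curvature import local_curvature_maxima, planar_curvature, space_curvature
from .frames import LocalFrame, SurfacePointCloud, TransectStrip, planar_strip
from .phantoms import estimate_normals
from .principal_curve import PrincipalCurve, fit_principal_curve, project_to_curve
from .pspline import (EqualityConstraint, PSplineModel, ShapeConstraintSpec,
                      constrain_through_points, fit_pspline, fit_shape_constrained)

__all__ = ["LipConfig", "LipStripResult", "LipCurves", "mouth_frame",
           "vertical_strips", "detect_lip_points", "resolve_multiple_candidates",
           "find_corners", "fit_lip_boundaries", "estimate_lip_boundaries",
           "curve_rms_distance"]


@dataclass
class LipConfig:
    n_strips: int = 50
    delta: float = 1.2              # strip slab half-thickness, mm
    strip_df: float = 8.0           # vertical principal curve / one-sided fits
    threshold: float = 5.0          # midline evidence threshold on |T|
    prelim_df: float = 18.0         # preliminary + midline 3-D curve df
    boundary_df: float = 25.0       # corner-constrained boundary fits
    boundary_nbasis: int = 30
    kappa_factor: float = 100.0
    corner_floor_quantile: float = 0.75
    corner_floor_frac: float = 0.35     # corner maxima must also reach this
                                        # fraction of the strongest maximum
    corner_end_mask: float = 0.04       # arc-length end fraction excluded from
                                        # the corner search (smoothing flare)
    candidate_floor_frac: float = 0.2   # drop ridge maxima below this fraction
                                        # of the strip's strongest ridge maximum
    candidate_end_mask: float = 0.05    # arc-length end fraction excluded from
                                        # the ridge-candidate search
    min_strip_points: int = 30
    span_quantiles: tuple = (0.02, 0.98)


@dataclass
class Candidate:
    s: float                # arc length on the strip's vertical curve
    point: np.ndarray       # 3-D location
    kappa: float            # ridge-sense curvature


@dataclass
class LipStripResult:
    index: int
    offset: float
    curve: PrincipalCurve | None
    strip: TransectStrip
    statistic: float | None = None
    midline_s: float | None = None
    midline_point: np.ndarray | None = None
    upper: list = field(default_factory=list)
    lower: list = field(default_factory=list)

    @property
    def has_midline(self) -> bool:
        return self.midline_point is not None


@dataclass
class LipCurves:
    """Final upper/midline/lower curves sharing the midline arc length."""

    s_grid: np.ndarray
    upper: np.ndarray
    midline: np.ndarray
    lower: np.ndarray
    corners: np.ndarray            # (2, 3): at sL then sR
    sL: float
    sR: float
    models: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"upper": self.upper, "midline": self.midline, "lower": self.lower}


def mouth_frame(cloud: SurfacePointCloud, up_hint=(0.0, 1.0, 0.0)) -> LocalFrame:
    """Global axis system of the mouth region from whole-region PCA.

    The first component n1 runs horizontally along the elongated mouth, the
    second n2 vertically, the third n3 along the surface normal.  n3 is
    oriented with the average of local surface normals; n2 toward
    ``up_hint`` (images are captured upright); n1 completes the triad.
    """
    centred = cloud.points - cloud.centroid
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    n1, n2, n3 = vt
    sub = SurfacePointCloud(cloud.points[np.linspace(0, len(cloud) - 1,
                                                     min(2000, len(cloud))).astype(int)])
    mean_normal = estimate_normals(sub).mean(axis=0)
    if n3 @ mean_normal < 0:
        n3 = -n3
    up = np.asarray(up_hint, dtype=float)
    if n2 @ up < 0:
        n2 = -n2
    n1 = np.cross(n2, n3)
    return LocalFrame(cloud.centroid, n1, n2, n3)


def vertical_strips(cloud: SurfacePointCloud, config: LipConfig | None = None,
                    frame: LocalFrame | None = None) -> list[TransectStrip]:
    """k parallel vertical strips |p' n1 - offset| <= delta across the mouth.

    Each strip is returned in a frame whose abscissa axis is the global
    vertical n2 and whose ordinate axis is the global normal n3, so the
    in-plane pattern is depth against height up the face.
    """
    config = config or LipConfig()
    frame = frame or mouth_frame(cloud)
    proj = (cloud.points - frame.origin) @ frame.n1
    lo, hi = np.quantile(proj, config.span_quantiles)
    offsets = np.linspace(lo, hi, config.n_strips)
    strips = []
    for off in offsets:
        sub_frame = LocalFrame(frame.origin + off * frame.n1,
                               frame.n2, frame.n1, frame.n3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            strips.append(planar_strip(cloud, sub_frame, config.delta, half=False))
    return strips


def detect_lip_points(strip: TransectStrip, config: LipConfig | None = None,
                      index: int = 0, offset: float = 0.0) -> LipStripResult:
    """Midline detection and ridge candidates for one vertical strip.

    The strip's principal curve supplies arc lengths s for the observed
    depths z; the change-point scan of z'(s) flags a midline crossing when
    max |T| exceeds the threshold.  Only then are ridge candidates collected:
    local maxima of ridge-sense curvature (bending away from the outward
    normal) on the curve segments above and below the midline.
    """
    config = config or LipConfig()
    result = LipStripResult(index, offset, None, strip)
    if len(strip) < config.min_strip_points:
        return result
    plane = strip.plane_coords
    curve = fit_principal_curve(plane, df=config.strip_df,
                                initial_index=strip.abscissa)
    result.curve = curve
    signal = TransectSignal(curve.s_data, strip.ordinate)
    try:
        scan = scan_derivative_change(signal, df=config.strip_df)
    except ValueError:
        return result
    det = detect_feature(scan, config.threshold)
    finite = np.isfinite(scan.statistic)
    result.statistic = (float(np.nanmax(np.abs(scan.statistic[finite])))
                        if finite.any() else None)
    if det is None:
        return result
    s_mid, _ = det
    result.midline_s = s_mid
    foot = curve(np.array([s_mid]))[0]
    result.midline_point = strip.to_world([foot[0]], [foot[1]])[0]
    ridge_profile = planar_curvature(curve).negated()
    maxima = local_curvature_maxima(ridge_profile, require_positive=True,
                                    end_mask_frac=config.candidate_end_mask)
    if maxima:
        floor = config.candidate_floor_frac * max(k for _, k in maxima)
        maxima = [(s, k) for s, k in maxima if k >= floor]
    for s, kappa in maxima:
        foot = curve(np.array([s]))[0]
        world = strip.to_world([foot[0]], [foot[1]])[0]
        cand = Candidate(float(s), world, float(kappa))
        if s > s_mid:
            result.upper.append(cand)
        elif s < s_mid:
            result.lower.append(cand)
    return result


def _fit_curve_through(points: np.ndarray, order_index: np.ndarray, df: float):
    df = min(df, len(points) - 2)
    if df < 3:
        raise ValueError(f"only {len(points)} points; too few to fit a curve")
    return fit_principal_curve(points, df=df, initial_index=order_index)


def resolve_multiple_candidates(results: list[LipStripResult], boundary: str,
                                config: LipConfig | None = None) -> list:
    """One candidate per strip: nearest, along the strip's vertical curve, to
    a preliminary boundary curve built from the single-candidate strips.

    Returns a list aligned with ``results`` containing a Candidate or None.
    """
    config = config or LipConfig()
    if boundary not in ("upper", "lower"):
        raise ValueError("boundary must be 'upper' or 'lower'")
    cand_lists = [getattr(r, boundary) for r in results]
    singles = [(r, cl[0]) for r, cl in zip(results, cand_lists) if len(cl) == 1]
    if not any(len(cl) > 1 for cl in cand_lists):
        return [cl[0] if cl else None for cl in cand_lists]
    if len(singles) < 4:
        raise ValueError(
            f"only {len(singles)} single-candidate strips; cannot build a "
            f"preliminary {boundary} boundary")
    pts = np.array([c.point for _, c in singles])
    order = np.array([r.offset for r, _ in singles])
    prelim = _fit_curve_through(pts, order, config.prelim_df)
    out = []
    for r, cl in zip(results, cand_lists):
        if not cl:
            out.append(None)
        elif len(cl) == 1:
            out.append(cl[0])
        else:
            # arc length of the preliminary curve's crossing of this strip,
            # measured along the strip's vertical curve
            vert3d = r.strip.to_world(r.curve.points_grid[:, 0],
                                      r.curve.points_grid[:, 1])
            d2 = ((prelim.points_grid[:, None, :] - vert3d[None, :, :]) ** 2).sum(axis=2)
            j = int(np.argmin(d2.min(axis=0)))
            s_prelim = r.curve.s_grid[j]
            out.append(select_nearest_candidate(cl, s_prelim))
    return out


def select_nearest_candidate(candidates, s_prelim: float):
    """Candidate whose arc length is closest to the preliminary crossing;
    exact ties resolve to the smaller arc length."""
    return min(candidates, key=lambda c: (abs(c.s - s_prelim), c.s))


def find_corners(results: list[LipStripResult], config: LipConfig | None = None):
    """Mouth corners from the 3-D curvature of the midline curve.

    A principal curve is fitted through the detected midline points; corners
    are the first and last local maxima of its space curvature (after
    masking the outer 2% and requiring the maxima to exceed the profile's
    upper quantile, which suppresses micro-maxima from noise).

    Returns (corner points (2,3), sL, sR, midline curve).
    """
    config = config or LipConfig()
    pts = np.array([r.midline_point for r in results if r.has_midline])
    offs = np.array([r.offset for r in results if r.has_midline])
    if len(pts) < 10:
        raise ValueError(f"only {len(pts)} midline points; need at least 10")
    # median screening along the strip sequence: a strip whose evidence was
    # marginal can place its midline point on the wrong feature, and a single
    # such outlier dominates the curvature profile
    order = np.argsort(offs, kind="stable")
    pts, offs = pts[order], offs[order]
    n = len(pts)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        lo, hi = max(0, i - 2), min(n, i + 3)
        nb = np.delete(np.arange(lo, hi), i - lo)
        # local linear prediction from the neighbours; the sequence is
        # locally linear even where it rises steeply at the corners
        A = np.column_stack([np.ones(len(nb)), offs[nb]])
        coef, *_ = np.linalg.lstsq(A, pts[nb], rcond=None)
        pred = coef[0] + coef[1] * offs[i]
        if np.linalg.norm(pts[i] - pred) > 2.5:
            keep[i] = False
    if keep.sum() >= 10:
        pts, offs = pts[keep], offs[keep]
    curve = _fit_curve_through(pts, offs, config.prelim_df)
    profile = space_curvature(curve)
    floor = float(np.nanquantile(profile.kappa, config.corner_floor_quantile))
    maxima = local_curvature_maxima(profile, floor=floor,
                                    end_mask_frac=config.corner_end_mask)
    if maxima:
        # corners carry very strong curvature; suppress weaker maxima such as
        # smoothing flare at the open ends of the midline curve
        strong = config.corner_floor_frac * max(k for _, k in maxima)
        maxima = [(s, k) for s, k in maxima if k >= strong]
    # merge ripple: maxima closer than 5 mm arc length describe one bend;
    # represent each cluster by its curvature-weighted position
    merged = []
    for s, k in maxima:
        if merged and s - merged[-1][-1][0] < 5.0:
            merged[-1].append((s, k))
        else:
            merged.append([(s, k)])
    peaks = []
    for cluster in merged:
        ss = np.array([s for s, _ in cluster])
        kk = np.array([k for _, k in cluster])
        peaks.append((float((ss * kk).sum() / kk.sum()), float(kk.max())))
    if len(peaks) < 2:
        raise ValueError("fewer than two curvature maxima on the midline curve")
    sL, _ = peaks[0]
    sR, _ = peaks[-1]
    corners = curve(np.array([sL, sR]))
    return corners, float(sL), float(sR), curve


def fit_lip_boundaries(results: list[LipStripResult],
                       upper, lower,
                       corners: np.ndarray, sL: float, sR: float,
                       midline_curve: PrincipalCurve,
                       frame: LocalFrame,
                       config: LipConfig | None = None) -> LipCurves:
    """Corner-constrained, shape-penalised boundary fits.

    All three curves share the midline's arc length: candidates are assigned
    s by projection onto the midline curve, points beyond the corners are
    discarded, and each coordinate is fitted by a P-spline forced through
    the corner values (the vertical coordinate additionally carries the
    monotonicity and second-derivative-trend penalties appropriate for an
    upper or lower lip).
    """
    config = config or LipConfig()
    local_corners = frame.to_local(corners)
    grid = np.linspace(sL, sR, 201)
    models: dict[str, list[PSplineModel]] = {}
    curves: dict[str, np.ndarray] = {}
    shape_specs = {"upper": ShapeConstraintSpec.upper_lip(),
                   "lower": ShapeConstraintSpec.lower_lip(), "midline": None}
    for name, cands in (("upper", upper), ("lower", lower), ("midline", None)):
        if name == "midline":
            s_vals = np.array([project_to_curve(midline_curve, r.midline_point)[0]
                               for r in results if r.has_midline])
            pts = np.array([r.midline_point for r in results if r.has_midline])
        else:
            # Discard strips lying beyond the corners (a strip is inside the
            # mouth iff its own midline point projects into [sL, sR]) and
            # share the strip's midline arc length as the candidate's s --
            # projecting a ridge point itself onto the curving midline would
            # pile near-corner candidates onto the corner arc length.
            got, s_list = [], []
            for r, c in zip(results, cands):
                if c is None or not r.has_midline:
                    continue
                s_strip = project_to_curve(midline_curve, r.midline_point)[0]
                if sL - 1e-9 <= s_strip <= sR + 1e-9:
                    got.append(c)
                    s_list.append(s_strip)
            if not got:
                raise ValueError(f"no {name} candidates between the corners")
            pts = np.array([c.point for c in got])
            s_vals = np.array(s_list)
        keep = (s_vals >= sL) & (s_vals <= sR)
        pts, s_vals = pts[keep], s_vals[keep]
        if len(pts) < 10:
            raise ValueError(f"only {len(pts)} {name} points between the corners")
        order = np.argsort(s_vals, kind="stable")
        s_vals, pts = s_vals[order], pts[order]
        local = frame.to_local(pts)
        df = min(config.boundary_df, len(pts) - 2)
        coord_models = []
        for j in range(3):
            con = EqualityConstraint(np.array([sL, sR]), local_corners[:, j])
            shapes = shape_specs[name] if j == 1 else None
            if shapes is not None:
                m = fit_shape_constrained(
                    s_vals, local[:, j], nbasis=config.boundary_nbasis, df=df,
                    constraint=con, shapes=shapes,
                    kappa_factor=config.kappa_factor, domain=(sL, sR))
            else:
                m = fit_pspline(s_vals, local[:, j],
                                nbasis=config.boundary_nbasis, df=df,
                                domain=(sL, sR))
                constrain_through_points(m, con, s_data=s_vals)
            coord_models.append(m)
        models[name] = coord_models
        curves[name] = frame.to_world(
            np.column_stack([m(grid) for m in coord_models]))
    return LipCurves(grid, curves["upper"], curves["midline"], curves["lower"],
                     corners, sL, sR, models)


@dataclass
class LipBoundaryResult:
    curves: LipCurves
    strip_results: list[LipStripResult]
    frame: LocalFrame
    report: dict


def estimate_lip_boundaries(cloud: SurfacePointCloud,
                            config: LipConfig | None = None,
                            frame: LocalFrame | None = None) -> LipBoundaryResult:
    """Full pipeline: strips -> change-point midlines -> candidates ->
    corners -> constrained boundary curves."""
    config = config or LipConfig()
    frame = frame or mouth_frame(cloud)
    strips = vertical_strips(cloud, config, frame)
    proj_off = [(s.frame.origin - frame.origin) @ frame.n1 for s in strips]
    results = [detect_lip_points(s, config, index=i, offset=off)
               for i, (s, off) in enumerate(zip(strips, proj_off))]
    upper = resolve_multiple_candidates(results, "upper", config)
    lower = resolve_multiple_candidates(results, "lower", config)
    corners, sL, sR, mid_curve = find_corners(results, config)
    curves = fit_lip_boundaries(results, upper, lower, corners, sL, sR,
                                mid_curve, frame, config)
    report = {
        "n_strips": len(strips),
        "n_midline_detected": sum(r.has_midline for r in results),
        "n_upper_multi": sum(len(r.upper) > 1 for r in results),
        "n_lower_multi": sum(len(r.lower) > 1 for r in results),
        "corner_separation_mm": float(np.linalg.norm(corners[1] - corners[0])),
    }
    return LipBoundaryResult(curves, results, frame, report)


def curve_rms_distance(est_points: np.ndarray, truth: np.ndarray,
                       n_samples: int = 51, axes: np.ndarray | None = None):
    """Root of the average squared distance between an estimated curve and a
    reference polyline over ``n_samples`` equally spaced points, with the
    per-axis decomposition (after orienting into the frame ``axes`` when
    given).

    Returns (overall_rms, per_axis_rms (3,)).
    """
    est = np.asarray(est_points, dtype=float)
    seg = np.linalg.norm(np.diff(est, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, s[-1], n_samples)
    samp = np.column_stack([np.interp(targets, s, est[:, j]) for j in range(3)])
    d2 = ((samp[:, None, :] - truth[None, :, :]) ** 2).sum(axis=2)
    j = np.argmin(d2, axis=1)
    diff = samp - truth[j]
    if axes is not None:
        diff = diff @ np.asarray(axes, dtype=float).T
    overall = float(np.sqrt(np.mean((diff ** 2).sum(axis=1))))
    per_axis = np.sqrt(np.mean(diff ** 2, axis=0))
    return overall, per_axis
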