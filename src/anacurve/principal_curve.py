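"""Principal curves in 2-D and 3-D.

A principal curve is a smooth curve that is self-consistent for a point set:
every curve point is the local average of the data points projecting onto it.
The classical alternating algorithm is used -- project the points onto the
current curve to obtain arc-length indices, then smooth each coordinate
against those indices -- initialised from the first linear principal
component.  Smoothing is by P-splines with the flexibility specified in
effective degrees of freedom, which is the quantity that matters rather than
the particular smoother mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .pspline import PSplineModel, fit_pspline

__all__ = ["PrincipalCurve", "fit_principal_curve", "project_to_curve", "extend_curve"]

GRID_SIZE = 512


@dataclass
class PrincipalCurve:
    """A fitted principal curve f(s) parameterised by arc length s in mm.

    ``coords`` holds one P-spline model per spatial coordinate, all sharing
    the arc-length argument.  ``s_grid``/``points_grid`` cache a dense
    evaluation used for projection queries.
    """

    coords: list[PSplineModel]
    s_grid: np.ndarray
    points_grid: np.ndarray
    s_data: np.ndarray
    df: float
    converged: bool
    n_iter: int
    projection_rms: float

    @property
    def dim(self) -> int:
        return len(self.coords)

    @property
    def smax(self) -> float:
        return float(self.s_grid[-1])

    def __call__(self, s, deriv: int = 0) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        return np.column_stack([m(s, deriv=deriv) for m in self.coords])

    evaluate = __call__

    def to_frame(self):
        import pandas as pd

        cols = ["x", "y", "z"][: self.dim]
        out = pd.DataFrame(self.points_grid, columns=cols)
        out.insert(0, "s", self.s_grid)
        return out


def _arclength_reparam(models: list[PSplineModel], lo: float, hi: float):
    """Dense evaluation with cumulative chord-length arc parameterisation."""
    t = np.linspace(lo, hi, GRID_SIZE)
    pts = np.column_stack([m(t) for m in models])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return t, s, pts


def _project_to_polyline(points: np.ndarray, grid_pts: np.ndarray, s: np.ndarray):
    """Exact foot-point projection onto the dense polyline.

    The nearest node supplies a bracket; the foot point is then computed on
    the two adjoining segments (ties resolve toward the smaller arc length).
    """
    n_pts = len(points)
    d2 = ((points[:, None, :] - grid_pts[None, :, :]) ** 2).sum(axis=2)
    idx = np.argmin(d2, axis=1)
    best_s = s[idx].astype(float)
    best_d2 = d2[np.arange(n_pts), idx]
    for off in (-1, 0):
        a = idx + off
        ok = (a >= 0) & (a + 1 < len(grid_pts))
        a = np.clip(a, 0, len(grid_pts) - 2)
        seg = grid_pts[a + 1] - grid_pts[a]
        len2 = (seg ** 2).sum(axis=1)
        len2[len2 == 0] = np.finfo(float).eps
        t = np.clip(((points - grid_pts[a]) * seg).sum(axis=1) / len2, 0.0, 1.0)
        foot = grid_pts[a] + t[:, None] * seg
        fd2 = ((points - foot) ** 2).sum(axis=1)
        fs = s[a] + t * (s[a + 1] - s[a])
        better = ok & ((fd2 < best_d2 - 1e-15) |
                       ((np.abs(fd2 - best_d2) <= 1e-15) & (fs < best_s)))
        best_d2 = np.where(better, fd2, best_d2)
        best_s = np.where(better, fs, best_s)
    return best_s, np.sqrt(best_d2), idx


def fit_principal_curve(points, df: float = 6.0, max_iter: int = 20,
                        tol: float = 1e-4, nbasis: int = 30,
                        initial_index=None) -> PrincipalCurve:
    """Fit a principal curve through 2-D or 3-D ``points``.

    Alternates projection and per-coordinate P-spline smoothing until the
    relative change in the total squared projection distance falls below
    ``tol``; the final curve is re-expressed in cumulative chord arc length.

    ``initial_index`` overrides the default first-principal-component
    initialisation with a caller-supplied ordering variable (one value per
    point), useful when the point set is symmetric about its first principal
    axis and the projection would otherwise fold.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim != 2 or X.shape[1] not in (2, 3):
        raise ValueError("points must be an (n, 2) or (n, 3) array")
    n, dim = X.shape
    if df < 2:
        raise ValueError("df must be at least 2")
    if n < df + 2:
        raise ValueError(f"need at least df+2={int(df) + 2} points, got {n}")
    if nbasis <= df + 1:
        nbasis = int(df) + 5
    nbasis = min(nbasis, max(n // 2, int(df) + 5))

    if initial_index is not None:
        s = np.asarray(initial_index, dtype=float).copy()
        if s.shape != (n,):
            raise ValueError("initial_index must supply one value per point")
    else:
        centred = X - X.mean(axis=0)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        s = centred @ vt[0]
    s = s - s.min()

    prev_ss = None
    converged = False
    it = 0
    models = None
    for it in range(1, max_iter + 1):
        span = s.max() - s.min()
        if span <= 0:
            raise ValueError("degenerate projection: all points share one index")
        models = [fit_pspline(s, X[:, j], nbasis=nbasis, df=df,
                              domain=(float(s.min()), float(s.max())))
                  for j in range(dim)]
        _, s_arc, pts = _arclength_reparam(models, float(s.min()), float(s.max()))
        s_new, dist, _ = _project_to_polyline(X, pts, s_arc)
        ss = float(np.sum(dist ** 2))
        s = s_new
        if prev_ss is not None:
            denom = max(prev_ss, 1e-12)
            if abs(prev_ss - ss) / denom < tol:
                converged = True
                break
        prev_ss = ss

    # final refit against the converged arc-length indices
    lo, hi = float(s.min()), float(s.max())
    if hi - lo <= 0:
        raise ValueError("degenerate projection: all points share one index")
    models = [fit_pspline(s, X[:, j], nbasis=nbasis, df=df, domain=(lo, hi))
              for j in range(dim)]
    _, s_arc, pts = _arclength_reparam(models, lo, hi)
    # shift/rescale the spline argument to true arc length via a refit
    t_grid = np.linspace(lo, hi, GRID_SIZE)
    s_of_t = np.interp(s, t_grid, s_arc)
    # refit against true arc length, iterating the projection/refit cycle a
    # few more times so the stored indices and fitted coordinates agree
    s_cur = s_of_t
    smax = float(s_arc[-1])
    for _ in range(3):
        models = [fit_pspline(s_cur, X[:, j], nbasis=nbasis, df=df,
                              domain=(0.0, smax)) for j in range(dim)]
        grid = np.linspace(0.0, smax, GRID_SIZE)
        pts = np.column_stack([m(grid) for m in models])
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        s_cur, dist, _ = _project_to_polyline(X, pts, arc)
        smax = float(arc[-1])
    s_final = s_cur
    return PrincipalCurve(models, grid, pts, s_final, float(df), converged, it,
                          float(np.sqrt(np.mean(dist ** 2))))


def project_to_curve(curve: PrincipalCurve, point) -> tuple[float, float, np.ndarray]:
    """Arc length, distance and foot point of the closest curve location.

    The dense evaluation grid supplies a bracket that is refined by continuous
    minimisation; exact ties resolve to the smallest arc length.
    """
    p = np.asarray(point, dtype=float)
    d2 = ((curve.points_grid - p) ** 2).sum(axis=1)
    i = int(np.argmin(d2))
    lo = curve.s_grid[max(i - 1, 0)]
    hi = curve.s_grid[min(i + 1, len(curve.s_grid) - 1)]

    def obj(s):
        return float(((curve([s])[0] - p) ** 2).sum())

    if hi > lo:
        res = minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-8})
        s_best = float(res.x)
        if obj(float(curve.s_grid[i])) < res.fun:
            s_best = float(curve.s_grid[i])
    else:
        s_best = float(curve.s_grid[i])
    foot = curve([s_best])[0]
    return s_best, float(np.linalg.norm(p - foot)), foot


def extend_curve(curve: PrincipalCurve, s_beyond: float) -> np.ndarray:
    """Linear extrapolation beyond the fitted range from the end point and slope."""
    s_beyond = float(s_beyond)
    if 0.0 < s_beyond < curve.smax:
        raise ValueError(f"s={s_beyond} lies inside the fitted range [0, {curve.smax:.3f}]")
    end = 0.0 if s_beyond <= 0.0 else curve.smax
    value = curve([end])[0]
    slope = curve([end], deriv=1)[0]
    return value + slope * (s_beyond - end)
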