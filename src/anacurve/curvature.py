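"""Curvature of fitted curves and extraction of local maxima.

Boundary evidence along a transect is carried by the curvature of the fitted
principal curve.  Planar curvature is signed -- positive when the curve bends
toward the ordinate direction (the outward surface normal in transect
coordinates), which is the sense of the crease where a breast mound joins the
chest wall; ridge crests bend the opposite way.  Space-curve curvature is
non-negative by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .principal_curve import PrincipalCurve

__all__ = ["CurvatureProfile", "planar_curvature", "space_curvature",
           "local_curvature_maxima"]

_SPEED_EPS = 1e-12


@dataclass
class CurvatureProfile:
    s: np.ndarray
    kappa: np.ndarray  # masked (nan) where the parameterisation speed vanishes
    curve: PrincipalCurve | None = None

    def __len__(self):
        return len(self.s)

    def negated(self) -> "CurvatureProfile":
        return CurvatureProfile(self.s, -self.kappa, self.curve)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"s": self.s, "kappa": self.kappa})


def planar_curvature(curve: PrincipalCurve, s=None) -> CurvatureProfile:
    """Signed curvature (x'y'' - x''y') / (x'^2 + y'^2)^(3/2) of a 2-D curve."""
    if curve.dim != 2:
        raise ValueError("planar_curvature requires a 2-D curve")
    s = curve.s_grid if s is None else np.asarray(s, dtype=float)
    d1 = curve(s, deriv=1)
    d2 = curve(s, deriv=2)
    speed2 = (d1 ** 2).sum(axis=1)
    num = d1[:, 0] * d2[:, 1] - d2[:, 0] * d1[:, 1]
    kappa = np.full_like(num, np.nan)
    ok = speed2 >= _SPEED_EPS
    kappa[ok] = num[ok] / speed2[ok] ** 1.5
    return CurvatureProfile(s, kappa, curve)


def space_curvature(curve: PrincipalCurve, s=None) -> CurvatureProfile:
    """Non-negative curvature |f' x f''| / |f'|^3 of a 3-D curve."""
    if curve.dim != 3:
        raise ValueError("space_curvature requires a 3-D curve")
    s = curve.s_grid if s is None else np.asarray(s, dtype=float)
    d1 = curve(s, deriv=1)
    d2 = curve(s, deriv=2)
    speed2 = (d1 ** 2).sum(axis=1)
    cross = np.cross(d1, d2)
    num = np.linalg.norm(cross, axis=1)
    kappa = np.full_like(num, np.nan)
    ok = speed2 >= _SPEED_EPS
    kappa[ok] = num[ok] / speed2[ok] ** 1.5
    return CurvatureProfile(s, kappa, curve)


def local_curvature_maxima(profile: CurvatureProfile, require_positive: bool = False,
                           end_mask_frac: float = 0.02,
                           floor: float | None = None) -> list[tuple[float, float]]:
    """Interior strict local maxima of a curvature profile.

    The outer ``end_mask_frac`` of the arc-length range is excluded (spline
    derivatives are unreliable at the ends).  On a plateau of equal values the
    first grid index is reported.  ``floor`` optionally drops maxima below a
    threshold; ``require_positive`` drops non-positive maxima.
    """
    s = np.asarray(profile.s, dtype=float)
    k = np.asarray(profile.kappa, dtype=float)
    if len(s) < 3:
        raise ValueError("profile needs at least 3 samples")
    lo = s[0] + end_mask_frac * (s[-1] - s[0])
    hi = s[-1] - end_mask_frac * (s[-1] - s[0])
    out = []
    i = 1
    n = len(s)
    while i < n - 1:
        if not np.isfinite(k[i]):
            i += 1
            continue
        # plateau handling: find run of equal values, report its first index
        j = i
        while j + 1 < n and np.isfinite(k[j + 1]) and k[j + 1] == k[i]:
            j += 1
        left = k[i - 1] if np.isfinite(k[i - 1]) else -np.inf
        right = k[j + 1] if j + 1 < n and np.isfinite(k[j + 1]) else -np.inf
        if k[i] > left and (j + 1 >= n or k[i] > right) and j + 1 < n:
            if lo <= s[i] <= hi:
                if not (require_positive and k[i] <= 0) and \
                        not (floor is not None and k[i] < floor):
                    out.append((float(s[i]), float(k[i])))
        i = j + 1
    return out
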