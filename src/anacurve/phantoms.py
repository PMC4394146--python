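"""Synthetic torso and lip surface phantoms with known ground truth.

The torso phantom is a pair of breast mounds on a cylindrical chest wall.
Each mound is a smooth dome with an erf-shaped flank, whose exact profile
curvature has a unique maximum on the outer flank; the circle through those
maxima is the analytically known boundary -- the crest of the junction
crease between mound and chest.  The lip phantom is a gently curved face
patch carrying two Gaussian-profile boundary ridges and a deep narrow
valley along the meeting line of the closed lips; the valley curls sharply
upward at the two mouth corners and fades into the cheek.  Ground-truth
curves are always the exact differential-geometric feature lines of the
analytic surface (curvature crests for ridges, the depth minimum for the
valley), extracted numerically to sub-grid accuracy, and the true corners
are the strongest curvature maxima of the exact valley-floor space curve.

Points are sampled unstructured (jittered grids) at a controllable density;
iid and spatially correlated ("orange peel") displacement noise along the
surface normals is available.  The same seed always reproduces the same
cloud, byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.interpolate import RegularGridInterpolator

from .frames import LandmarkSet, SurfacePointCloud

__all__ = ["PhantomSpec", "GroundTruth", "make_torso_phantom", "make_lip_phantom",
           "add_surface_noise", "side_landmarks", "estimate_normals"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, sampling and noise parameters for a synthetic surface."""

    kind: str = "torso"
    # torso geometry (mm)
    breast_radius: float = 48.0     # radial location of the mound flank (erf step centre)
    chest_radius: float = 220.0
    apex_height: float = 26.0       # flank step height; apex adds the dome on top
    flank_width: float = 9.0        # erf flank scale; sets the sharpness of the junction
    dome_height: float = 8.0        # extra rounded dome so prom is a genuine prominence
    mound_offset: float = 85.0      # lateral distance of each mound centre from the midline
    eccentricity: float = 1.0       # >1 compresses the mound vertically (elliptic boundary)
    shoulder_ridge: bool = False
    # lip geometry (mm)
    mouth_half_width: float = 30.0
    ridge_height: float = 2.0       # upper boundary ridge (the more marked one)
    lower_ridge_height: float = 1.6
    ridge_width: float = 4.0        # Gaussian scale of the boundary ridges
    ridge_sep_upper: float = 10.0   # vertical separation of ridge crest from the midline
    ridge_sep_lower: float = 13.0
    valley_depth: float = 2.5
    valley_width: float = 2.5       # Gaussian scale of the valley cross-section
    notch_depth: float = 0.0        # optional cupid's-bow notch on the upper boundary
    # sampling and noise
    density: float | None = None    # points per mm^2; kind-specific default if None
    noise_sd: float = 0.0
    orange_peel_amplitude: float = 0.0
    correlation_length: float = 8.0
    seed: int = 0

    _POSITIVE = ("breast_radius", "chest_radius", "apex_height", "flank_width",
                 "mound_offset", "mouth_half_width", "ridge_sep_upper",
                 "ridge_sep_lower", "valley_width", "ridge_width",
                 "correlation_length")
    # valley_rounding may be zero (a true crease) but not negative
    _NONNEG = ("ridge_height", "lower_ridge_height", "valley_depth", "notch_depth",
               "noise_sd", "orange_peel_amplitude", "eccentricity", "dome_height")

    def __post_init__(self):
        if self.kind not in ("torso", "lip"):
            raise ValueError(f"kind must be 'torso' or 'lip', got {self.kind!r}")
        for name in self._POSITIVE:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive, got {getattr(self, name)}")
        for name in self._NONNEG:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.density is not None and not self.density > 0:
            raise ValueError(f"density must be strictly positive, got {self.density}")

    @staticmethod
    def torso(**kw) -> "PhantomSpec":
        return PhantomSpec(kind="torso", **kw)

    @staticmethod
    def lip(high_density: bool = False, **kw) -> "PhantomSpec":
        if high_density and "density" not in kw:
            kw["density"] = 41.7
        return PhantomSpec(kind="lip", **kw)

    @property
    def effective_density(self) -> float:
        if self.density is not None:
            return self.density
        return 0.37 if self.kind == "torso" else 6.0


@dataclass
class GroundTruth:
    """True boundary polylines, landmark coordinates and (for lips) corners."""

    curves: dict[str, np.ndarray | None]
    landmarks: LandmarkSet
    corners: np.ndarray | None = None  # (2, 3): left then right mouth corner


# ---------------------------------------------------------------------------
# torso

def _mound_profile(spec: PhantomSpec):
    """Smooth dome-plus-erf-flank mound height profile h(rho).

    h(rho) = H/2 * (1 - erf((rho - rho0)/(sigma*sqrt(2)))) + D * exp(-rho^2/(2*sigma_d^2))

    The flank of the erf step carries a unique maximum of the profile
    curvature h'' / (1 + h'^2)^{3/2} on its outer side; its radial location
    rho_star (solved from the exact derivatives) defines the ground-truth
    boundary circle -- the crest of the junction crease between mound and
    chest wall.  Returns (h, rho_star, h(rho_star)).
    """
    from scipy.optimize import minimize_scalar
    from scipy.special import erf

    H, rho0, sig = spec.apex_height, spec.breast_radius, spec.flank_width
    D = spec.dome_height
    sig_d = 0.45 * rho0

    def h(rho):
        rho = np.asarray(rho, dtype=float)
        return (H * 0.5 * (1.0 - erf((rho - rho0) / (sig * np.sqrt(2.0))))
                + D * np.exp(-rho ** 2 / (2 * sig_d ** 2)))

    def d1(rho):
        return (-H / (sig * np.sqrt(2 * np.pi)) * np.exp(-(rho - rho0) ** 2 / (2 * sig ** 2))
                - D * rho / sig_d ** 2 * np.exp(-rho ** 2 / (2 * sig_d ** 2)))

    def d2(rho):
        return (H * (rho - rho0) / (sig ** 3 * np.sqrt(2 * np.pi))
                * np.exp(-(rho - rho0) ** 2 / (2 * sig ** 2))
                + D * (rho ** 2 / sig_d ** 2 - 1.0) / sig_d ** 2
                * np.exp(-rho ** 2 / (2 * sig_d ** 2)))

    def kappa(rho):
        return d2(rho) / (1.0 + d1(rho) ** 2) ** 1.5

    res = minimize_scalar(lambda r_: -kappa(r_), bounds=(rho0, rho0 + 4 * sig),
                          method="bounded", options={"xatol": 1e-8})
    rho_star = float(res.x)
    return h, rho_star, float(h(rho_star))


_TORSO_DOMAIN = (-170.0, 170.0, -90.0, 150.0)  # (u_lo, u_hi, v_lo, v_hi)
_SSN_V, _XIPHO_V = 120.0, -45.0


def _torso_surface(spec: PhantomSpec):
    """Return map (u, v) -> 3-D point, plus profile info."""
    Rc = spec.chest_radius
    h, rho_star, _ = _mound_profile(spec)
    centres = [(-spec.mound_offset, 0.0), (spec.mound_offset, 0.0)]
    ecc = spec.eccentricity

    def height(u, v):
        out = np.zeros_like(np.asarray(u, dtype=float))
        for (u0, v0) in centres:
            rho = np.sqrt((u - u0) ** 2 + (ecc * (v - v0)) ** 2)
            out = out + h(rho)
        if spec.shoulder_ridge:
            vr = rho_star / ecc * 0.95
            for (u0, v0) in centres:
                band = np.exp(-((v - (v0 + vr)) ** 2) / (2 * 8.0 ** 2))
                lat = np.exp(-((u - u0) ** 2) / (2 * 40.0 ** 2))
                out = out + 15.0 * band * lat
        return out

    def embed(u, v):
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        phi = u / Rc
        nrm = np.stack([np.sin(phi), np.zeros_like(phi), np.cos(phi)], axis=-1)
        wall = np.stack([Rc * np.sin(phi), v, Rc * np.cos(phi) - Rc], axis=-1)
        return wall + height(u, v)[..., None] * nrm

    return embed, height, rho_star, centres


def _jittered_samples(rng, lo_u, hi_u, lo_v, hi_v, density):
    spacing = 1.0 / np.sqrt(density)
    nu = int(np.floor((hi_u - lo_u) / spacing))
    nv = int(np.floor((hi_v - lo_v) / spacing))
    gu, gv = np.meshgrid(lo_u + spacing * (np.arange(nu) + 0.5),
                         lo_v + spacing * (np.arange(nv) + 0.5), indexing="ij")
    ju = rng.uniform(-0.5, 0.5, gu.shape) * spacing
    jv = rng.uniform(-0.5, 0.5, gv.shape) * spacing
    return (gu + ju).ravel(), (gv + jv).ravel()


def make_torso_phantom(spec: PhantomSpec):
    """Torso phantom: cloud, named landmarks and true boundary circles.

    Landmark names carry a side suffix (_l / _r by the sign of x) for the
    per-breast points prom, med, lat, inf; ssn and xipho sit on the midline.
    """
    if spec.kind != "torso":
        raise ValueError(f"spec.kind must be 'torso', got {spec.kind!r}")
    embed, _, rho_star, centres = _torso_surface(spec)
    lo_u, hi_u, lo_v, hi_v = _TORSO_DOMAIN
    rng = np.random.default_rng(spec.seed)
    u, v = _jittered_samples(rng, lo_u, hi_u, lo_v, hi_v, spec.effective_density)
    pts = embed(u, v)
    cloud = SurfacePointCloud(pts)
    if spec.noise_sd > 0 or spec.orange_peel_amplitude > 0:
        cloud = add_surface_noise(cloud, spec.noise_sd, spec.orange_peel_amplitude,
                                  spec.correlation_length,
                                  seed=int(rng.integers(2 ** 31)))

    ecc = spec.eccentricity
    names, lpts = [], []
    curves = {}
    for (u0, v0) in centres:
        side = "l" if u0 < 0 else "r"
        toward_mid = -np.sign(u0)
        names += [f"prom_{side}", f"med_{side}", f"lat_{side}", f"inf_{side}"]
        lpts += [embed(u0, v0)[()],
                 embed(u0 + toward_mid * rho_star, v0)[()],
                 embed(u0 - toward_mid * rho_star, v0)[()],
                 embed(u0, v0 - rho_star / ecc)[()]]
        psi = np.linspace(0.0, 2 * np.pi, 721)
        curves[side] = embed(u0 + rho_star * np.cos(psi),
                             v0 + rho_star * np.sin(psi) / ecc)
    names += ["ssn", "xipho"]
    lpts += [embed(0.0, _SSN_V)[()], embed(0.0, _XIPHO_V)[()]]
    landmarks = LandmarkSet(names, np.asarray(lpts))
    return cloud, landmarks, GroundTruth(curves, landmarks)


def side_landmarks(landmarks: LandmarkSet, side: str) -> LandmarkSet:
    """Standard six-name landmark set (prom, med, lat, inf, ssn, xipho) for one breast."""
    if side not in ("l", "r"):
        raise ValueError("side must be 'l' or 'r'")
    names, pts = [], []
    for base in ("prom", "med", "lat", "inf"):
        names.append(base)
        pts.append(landmarks[f"{base}_{side}"])
    for base in ("ssn", "xipho"):
        names.append(base)
        pts.append(landmarks[base])
    return LandmarkSet(names, np.asarray(pts))


# ---------------------------------------------------------------------------
# lips

_LIP_DOMAIN = (-45.0, 45.0, -20.0, 20.0)
_TURN_INSET = 2.0       # the crease curls upward this far inside the nominal width
_TURN_HALF = 1.5        # half-width of the quadratic turn blend, mm
_OUT_SLOPE = 1.2        # upward slope of the crease past the turn
_FADE_START = 1.0       # crease starts fading this far beyond the nominal width
_FADE_LEN = 4.0


def _smoothstep(t):
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _lip_fields(spec: PhantomSpec):
    w = spec.mouth_half_width
    smile = 1.5  # gentle upward bow of the meeting line, mm

    def y_mid_inner(x):
        return smile * (1.0 - (x / w) ** 2)

    def y_path(x):
        """Valley centreline: a gentle bow that curls sharply upward at the
        mouth corners (a quadratic hinge just inside the nominal width, where
        the crease is still at full depth)."""
        x = np.asarray(x, dtype=float)
        inner = y_mid_inner(np.clip(x, -w, w))
        d = np.abs(x) - (w - _TURN_INSET)
        b = _TURN_HALF
        hinge = np.where(d < -b, 0.0,
                         np.where(d > b, d, (d + b) ** 2 / (4 * b)))
        return inner + _OUT_SLOPE * hinge

    def shape_fac(x):
        # parabolic bow: the boundary curves meet the corners at finite slope
        return np.clip(1.0 - (np.asarray(x, dtype=float) / w) ** 2, 0.0, None)

    def y_upper(x):
        y = y_mid_inner(x) + spec.ridge_sep_upper * shape_fac(x)
        if spec.notch_depth > 0:
            y = y - spec.notch_depth * np.exp(-(np.asarray(x) / (w / 6.0)) ** 2)
        return y

    def y_lower(x):
        return y_mid_inner(x) - spec.ridge_sep_lower * shape_fac(x)

    def depth_taper(x):
        # the crease holds full depth through the corner turn, then fades as
        # it runs up into the cheek
        ax = np.abs(np.asarray(x, dtype=float))
        return _smoothstep((w + _FADE_START + _FADE_LEN - ax) / _FADE_LEN)

    def ridge_amp(x):
        # full strength over the mouth, fading only in the last few mm
        ax = np.abs(np.asarray(x, dtype=float))
        return _smoothstep((w - ax) / 4.0)

    def ridge_width(x):
        # the lip margins become finer as they converge on the corners
        return spec.ridge_width * (0.3 + 0.7 * np.sqrt(shape_fac(x)))

    def z_surface(x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        z = -(x ** 2) / (2 * 250.0) - (y ** 2) / (2 * 300.0)
        d = y - y_path(x)
        z = z - spec.valley_depth * depth_taper(x) * np.exp(
            -d ** 2 / (2 * spec.valley_width ** 2))
        amp = ridge_amp(x)
        sr2 = 2 * ridge_width(x) ** 2
        z = z + spec.ridge_height * amp * np.exp(-((y - y_upper(x)) ** 2) / sr2)
        z = z + spec.lower_ridge_height * amp * np.exp(-((y - y_lower(x)) ** 2) / sr2)
        return z

    return y_path, y_upper, y_lower, z_surface


def make_lip_phantom(spec: PhantomSpec):
    """Lip phantom: cloud, 7 anatomical landmarks and three true boundary curves.

    Ground-truth curves 'upper', 'midline', 'lower' meet pairwise at the two
    corners; with ridge heights of zero the corresponding boundary curves are
    reported as absent (None) while the valley midline is retained.
    """
    if spec.kind != "lip":
        raise ValueError(f"spec.kind must be 'lip', got {spec.kind!r}")
    y_path, y_upper, y_lower, z_surface = _lip_fields(spec)
    lo_x, hi_x, lo_y, hi_y = _LIP_DOMAIN
    rng = np.random.default_rng(spec.seed)
    x, y = _jittered_samples(rng, lo_x, hi_x, lo_y, hi_y, spec.effective_density)
    pts = np.column_stack([x, y, z_surface(x, y)])
    cloud = SurfacePointCloud(pts)
    if spec.noise_sd > 0 or spec.orange_peel_amplitude > 0:
        cloud = add_surface_noise(cloud, spec.noise_sd, spec.orange_peel_amplitude,
                                  spec.correlation_length,
                                  seed=int(rng.integers(2 ** 31)))

    w = spec.mouth_half_width

    def on_surface(xc, yc):
        return np.stack([xc, yc, z_surface(xc, yc)], axis=-1)

    def extreme_line(guide, half_band, mode, xs):
        """Exact feature line of the z field: per x, the ridge-sense curvature
        crest (mode 'crest') or depth minimum (mode 'valley') of the vertical
        profile within a band around a guide curve, refined to sub-grid
        accuracy."""
        ny = 901
        offs = np.linspace(-half_band, half_band, ny)
        yy = guide(xs)[:, None] + offs[None, :]
        xx = np.broadcast_to(xs[:, None], yy.shape)
        z = z_surface(xx, yy)
        h = offs[1] - offs[0]
        if mode == "valley":
            score = -z
        else:
            d1 = np.gradient(z, h, axis=1)
            d2 = np.gradient(d1, h, axis=1)
            score = -d2 / (1.0 + d1 ** 2) ** 1.5
        j = np.argmax(score[:, 2:-2], axis=1) + 2
        rows = np.arange(len(xs))
        s0, s1, s2 = (score[rows, j - 1], score[rows, j], score[rows, j + 1])
        denom = s0 - 2 * s1 + s2
        shift = np.where(np.abs(denom) > 1e-12, 0.5 * (s0 - s2) / denom, 0.0)
        y_star = yy[rows, j] + np.clip(shift, -1, 1) * h
        return on_surface(xs, y_star)

    # true corners: first and last curvature maxima of the exact valley-floor
    # space curve (the crease curls sharply upward there)
    xs_v = np.linspace(-(w + 3.0), w + 3.0, 2401)
    valley_line = extreme_line(y_path, 4.0, "valley", xs_v)
    t1 = np.gradient(valley_line, axis=0)
    t2 = np.gradient(t1, axis=0)
    speed2 = (t1 ** 2).sum(axis=1)
    kap_v = np.linalg.norm(np.cross(t1, t2), axis=1) / speed2 ** 1.5
    half = len(xs_v) // 2
    turn = np.abs(np.abs(xs_v) - (w - _TURN_INSET)) <= 3.0
    iL = np.argmax(np.where(turn[:half], kap_v[:half], -np.inf))
    iR = half + np.argmax(np.where(turn[half:], kap_v[half:], -np.inf))
    corner_l, corner_r = valley_line[iL], valley_line[iR]
    x_cl, x_cr = valley_line[iL, 0], valley_line[iR, 0]
    corners = np.vstack([corner_l, corner_r])

    eps = 0.5
    xs_in = np.linspace(x_cl + eps, x_cr - eps, 401)

    def with_corners(line):
        return np.vstack([corner_l, line, corner_r])

    midline_t = with_corners(valley_line[(xs_v >= x_cl + eps) & (xs_v <= x_cr - eps)])
    upper_t = (with_corners(extreme_line(y_upper, 6.0, "crest", xs_in))
               if spec.ridge_height > 0 else None)
    lower_t = (with_corners(extreme_line(y_lower, 6.0, "crest", xs_in))
               if spec.lower_ridge_height > 0 else None)
    curves = {"midline": midline_t, "upper": upper_t, "lower": lower_t}

    def on_curve(curve, xq):
        k = np.argmin(np.abs(curve[:, 0] - xq))
        return curve[k]

    lnames = ["ch_l", "ch_r", "cphl_l", "cphl_r", "ls", "li", "sto"]
    up_ref = upper_t if upper_t is not None else midline_t
    lo_ref = lower_t if lower_t is not None else midline_t
    lpts = np.vstack([
        corner_l, corner_r,
        on_curve(up_ref, -w / 3.0), on_curve(up_ref, w / 3.0),
        on_curve(up_ref, 0.0), on_curve(lo_ref, 0.0), on_curve(midline_t, 0.0),
    ])
    landmarks = LandmarkSet(lnames, lpts)
    return cloud, landmarks, GroundTruth(curves, landmarks, corners)


# ---------------------------------------------------------------------------
# noise

def estimate_normals(cloud: SurfacePointCloud, k: int = 12) -> np.ndarray:
    """Per-point unit normals from k-nearest-neighbour PCA, oriented away
    from the cloud centroid."""
    _, idx = cloud.tree.query(cloud.points, k=k)
    nb = cloud.points[idx]
    centred = nb - nb.mean(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    normals = vt[:, 2, :]
    outward = cloud.points - cloud.centroid
    flip = np.einsum("ij,ij->i", normals, outward) < 0
    normals[flip] *= -1.0
    return normals


def add_surface_noise(cloud: SurfacePointCloud, sd: float = 0.0,
                      orange_peel_amplitude: float = 0.0,
                      correlation_length: float = 8.0,
                      seed: int = 0) -> SurfacePointCloud:
    """Displace points along their surface normals by iid noise plus a smooth
    correlated ("orange peel") field.

    The correlated field is Gaussian-kernel-smoothed white noise sampled over
    the two dominant tangential coordinates of the cloud; its autocorrelation
    falls to 1/e at ``correlation_length`` and its marginal sd equals
    ``orange_peel_amplitude``.
    """
    if sd < 0 or orange_peel_amplitude < 0:
        raise ValueError("noise sd and orange-peel amplitude must be non-negative")
    if sd == 0 and orange_peel_amplitude == 0:
        return cloud
    rng = np.random.default_rng(seed)
    normals = estimate_normals(cloud)
    disp = np.zeros(len(cloud))
    if sd > 0:
        disp += sd * rng.standard_normal(len(cloud))
    if orange_peel_amplitude > 0:
        centred = cloud.points - cloud.centroid
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        uv = centred @ vt[:2].T
        pitch = correlation_length / 4.0
        sigma_cells = (correlation_length / 2.0) / pitch
        lo = uv.min(axis=0) - 2 * correlation_length
        hi = uv.max(axis=0) + 2 * correlation_length
        shape = (np.ceil((hi - lo) / pitch).astype(int) + 1)
        white = rng.standard_normal(tuple(shape))
        smooth = gaussian_filter(white, sigma=sigma_cells, mode="wrap")
        smooth /= smooth.std()
        interp = RegularGridInterpolator(
            (lo[0] + pitch * np.arange(shape[0]), lo[1] + pitch * np.arange(shape[1])),
            smooth, method="linear")
        disp += orange_peel_amplitude * interp(uv)
    return SurfacePointCloud(cloud.points + disp[:, None] * normals,
                             cloud.colors)
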