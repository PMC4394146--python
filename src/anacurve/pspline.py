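"""Penalised B-spline (P-spline) smoothing with equality and shape constraints.

P-splines combine a modest B-spline basis with a difference penalty on the
coefficients (Eilers & Marx style).  The amount of smoothing is most naturally
specified in effective degrees of freedom -- the trace of the smoother ("hat")
matrix -- and the smoothing parameter ``lambda`` is solved to match a requested
df.  Two extensions needed for anatomical boundary curves are provided:

* exact interpolation constraints ``A beta = c`` (forcing a curve through the
  mouth corners, say), solved in closed form against the penalised Gram matrix;
* soft shape penalties driving monotonicity and a prescribed second-derivative
  pattern over chosen arc-length regions, implemented as iteratively reweighted
  difference penalties with 0/1 violation masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.interpolate import BSpline
from scipy.optimize import brentq

__all__ = [
    "BSplineBasis",
    "PSplineModel",
    "EqualityConstraint",
    "ShapeConstraintSpec",
    "fit_pspline",
    "constrain_through_points",
    "fit_shape_constrained",
    "difference_matrix",
    "lambda_for_df",
]


def difference_matrix(n: int, order: int) -> np.ndarray:
    """Order-``order`` difference operator on a coefficient vector of length ``n``."""
    return np.diff(np.eye(n), n=order, axis=0)


@dataclass(frozen=True)
class BSplineBasis:
    """Cubic (by default) B-spline basis on equally spaced knots over a domain."""

    lo: float
    hi: float
    nbasis: int
    degree: int = 3

    def __post_init__(self):
        if self.nbasis <= self.degree + 1:
            raise ValueError(f"nbasis must exceed degree+1, got {self.nbasis}")
        if not self.hi > self.lo:
            raise ValueError("domain must have positive length")

    @property
    def knots(self) -> np.ndarray:
        ninter = self.nbasis - self.degree
        step = (self.hi - self.lo) / ninter
        return self.lo + step * np.arange(-self.degree, ninter + self.degree + 1)

    def design(self, s, deriv: int = 0) -> np.ndarray:
        """Design matrix of basis functions (or their derivatives) at ``s``.

        Evaluation is clamped to the domain, so querying slightly outside due
        to round-off is safe.
        """
        s = np.clip(np.atleast_1d(np.asarray(s, dtype=float)), self.lo, self.hi)
        spl = BSpline(self.knots, np.eye(self.nbasis), self.degree)
        if deriv:
            spl = spl.derivative(deriv)
        return spl(s)


@dataclass(frozen=True)
class EqualityConstraint:
    """Force the fitted curve through given (s, value) pairs: ``A beta = c``."""

    s: np.ndarray
    values: np.ndarray

    def matrix(self, basis: BSplineBasis) -> np.ndarray:
        A = basis.design(self.s)
        if np.linalg.matrix_rank(A) < A.shape[0]:
            raise ValueError("constraint rows are linearly dependent")
        return A


@dataclass(frozen=True)
class ShapeConstraintSpec:
    """Regions (as arc-length fractions) with required monotonicity and
    second-derivative-change direction.

    ``monotone``: list of (frac_lo, frac_hi, direction) with direction +1 for
    increasing, -1 for decreasing first differences of the fit.
    ``curvature_trend``: list of (frac_lo, frac_hi, direction) with direction
    +1 when the second derivative must be increasing over the region, -1 when
    decreasing.
    """

    monotone: tuple = ()
    curvature_trend: tuple = ()

    @staticmethod
    def upper_lip(frac: float = 0.4) -> "ShapeConstraintSpec":
        # rises toward the centre then falls; second derivative decreasing
        # then increasing near the corners
        return ShapeConstraintSpec(
            monotone=((0.0, frac, +1), (1.0 - frac, 1.0, -1)),
            curvature_trend=((0.0, frac, -1), (1.0 - frac, 1.0, +1)),
        )

    @staticmethod
    def lower_lip(frac: float = 0.4) -> "ShapeConstraintSpec":
        return ShapeConstraintSpec(
            monotone=((0.0, frac, -1), (1.0 - frac, 1.0, +1)),
            curvature_trend=((0.0, frac, +1), (1.0 - frac, 1.0, -1)),
        )


@dataclass
class PSplineModel:
    basis: BSplineBasis
    lam: float
    beta: np.ndarray
    df: float
    kappa: float = 0.0
    beta_unconstrained: np.ndarray | None = None
    converged: bool = True
    n_iter: int = 0

    def __call__(self, s, deriv: int = 0) -> np.ndarray:
        return self.basis.design(s, deriv=deriv) @ self.beta

    predict = __call__

    def predict_extrapolate(self, s) -> np.ndarray:
        """Evaluate, extending linearly (endpoint value + slope) outside the domain."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        out = self(s)
        for bound, side in ((self.basis.lo, s < self.basis.lo), (self.basis.hi, s > self.basis.hi)):
            if np.any(side):
                v = self([bound])[0]
                d = self([bound], deriv=1)[0]
                out[side] = v + d * (s[side] - bound)
        return out

    def to_dict(self) -> dict:
        return {
            "lo": self.basis.lo,
            "hi": self.basis.hi,
            "nbasis": self.basis.nbasis,
            "degree": self.basis.degree,
            "lambda": self.lam,
            "kappa": self.kappa,
            "beta": self.beta.tolist(),
            "df": self.df,
        }

    @staticmethod
    def from_dict(d: dict) -> "PSplineModel":
        basis = BSplineBasis(d["lo"], d["hi"], d["nbasis"], d["degree"])
        return PSplineModel(basis, d["lambda"], np.asarray(d["beta"]), d["df"], d.get("kappa", 0.0))


def _df_function(BtB: np.ndarray, P: np.ndarray):
    """Return df(lambda) = tr[(B'B + lam P)^-1 B'B] via a generalised eigenproblem."""
    p = BtB.shape[0]
    ridge = 1e-10 * (np.trace(BtB) / p + 1.0)
    G = BtB + ridge * np.eye(p)
    mu = linalg.eigh(P, G, eigvals_only=True)
    mu = np.clip(mu, 0.0, None)

    def df(lam: float) -> float:
        return float(np.sum(1.0 / (1.0 + lam * mu)))

    return df


def lambda_for_df(BtB: np.ndarray, P: np.ndarray, target_df: float,
                  lo: float = 1e-9, hi: float = 1e12) -> float:
    """Solve for lambda so the smoother-matrix trace equals ``target_df``."""
    df = _df_function(BtB, P)
    if not df(lo) > target_df:
        raise ValueError(
            f"requested df={target_df} exceeds the maximum attainable {df(lo):.2f}")
    if df(hi) > target_df:
        raise ValueError(f"requested df={target_df} below the penalty null-space dimension")
    loglam = brentq(lambda t: df(10.0 ** t) - target_df, np.log10(lo), np.log10(hi), xtol=1e-10)
    return 10.0 ** loglam


def _solve(Gpen: np.ndarray, Btx: np.ndarray) -> np.ndarray:
    try:
        c, low = linalg.cho_factor(Gpen)
        return linalg.cho_solve((c, low), Btx)
    except linalg.LinAlgError:
        # nearly singular: retry with a slightly stronger regulariser
        bumped = Gpen + 1e-8 * (np.trace(Gpen) / len(Gpen)) * np.eye(len(Gpen))
        try:
            c, low = linalg.cho_factor(bumped)
            return linalg.cho_solve((c, low), Btx)
        except linalg.LinAlgError as exc:
            raise linalg.LinAlgError("penalised system is rank deficient") from exc


def fit_pspline(s, x, nbasis: int = 30, df: float | None = None,
                lam: float | None = None, degree: int = 3,
                domain: tuple[float, float] | None = None) -> PSplineModel:
    """Penalised least-squares B-spline fit of ``x`` against ``s``.

    Exactly one of ``df`` (effective degrees of freedom; lambda is solved so
    the hat-matrix trace matches it) or ``lam`` must be given.
    """
    s = np.asarray(s, dtype=float)
    x = np.asarray(x, dtype=float)
    if s.shape != x.shape or s.ndim != 1:
        raise ValueError("s and x must be 1-D arrays of equal length")
    if (df is None) == (lam is None):
        raise ValueError("specify exactly one of df or lam")
    if domain is None:
        domain = (float(s.min()), float(s.max()))
    basis = BSplineBasis(domain[0], domain[1], nbasis, degree)
    B = basis.design(s)
    P = difference_matrix(nbasis, 2)
    P = P.T @ P
    BtB = B.T @ B
    if df is not None:
        if len(s) <= df:
            raise ValueError(f"need more than df={df} observations, got {len(s)}")
        lam = lambda_for_df(BtB, P, df)
        achieved = df
    else:
        achieved = float(np.sum(1.0 / (1.0 + lam * np.clip(
            linalg.eigh(P, BtB + 1e-10 * (np.trace(BtB) / nbasis + 1) * np.eye(nbasis),
                        eigvals_only=True), 0, None))))
    ridge = 1e-13 * (np.trace(BtB) / nbasis + 1.0)
    beta = _solve(BtB + lam * P + ridge * np.eye(nbasis), B.T @ x)
    return PSplineModel(basis, float(lam), beta, float(achieved))


def _penalised_gram(basis: BSplineBasis, B: np.ndarray, lam: float,
                    kappa: float = 0.0, V1: np.ndarray | None = None,
                    V2: np.ndarray | None = None) -> np.ndarray:
    p = basis.nbasis
    D1 = difference_matrix(p, 1)
    D2 = difference_matrix(p, 2)
    G = B.T @ B + lam * (D2.T @ D2)
    if kappa and V1 is not None:
        G = G + kappa * (D1.T @ (V1[:, None] * D1))
    if kappa and V2 is not None:
        G = G + kappa * (D2.T @ (V2[:, None] * D2))
    return G + 1e-13 * (np.trace(B.T @ B) / p + 1.0) * np.eye(p)


def constrain_through_points(model: PSplineModel, constraint: EqualityConstraint,
                             B: np.ndarray | None = None,
                             Gpen: np.ndarray | None = None,
                             s_data=None) -> np.ndarray:
    """Adjust fitted coefficients to satisfy ``A beta = c`` exactly.

    beta_c = beta + G^-1 A' [A G^-1 A']^-1 (c - A beta), with G the penalised
    Gram matrix of the fit.  Returns the constrained coefficient vector and
    stores it on the model.
    """
    A = constraint.matrix(model.basis)
    c = np.asarray(constraint.values, dtype=float)
    if A.shape[0] != c.shape[0]:
        raise ValueError("constraint matrix and targets disagree in size")
    if Gpen is None:
        if B is None:
            if s_data is None:
                raise ValueError("need B, Gpen or s_data to rebuild the penalised Gram")
            B = model.basis.design(np.asarray(s_data, dtype=float))
        Gpen = _penalised_gram(model.basis, B, model.lam)
    GiAt = np.linalg.solve(Gpen, A.T)
    bracket = A @ GiAt
    try:
        mult = np.linalg.solve(bracket, c - A @ model.beta)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular constraint bracket matrix") from exc
    beta_c = model.beta + GiAt @ mult
    model.beta_unconstrained = model.beta.copy()
    model.beta = beta_c
    return beta_c


def _region_masks(basis: BSplineBasis, regions, n_rows: int) -> list[tuple[np.ndarray, int]]:
    """Map arc-length-fraction regions to difference-operator rows.

    Row j of an order-d difference operator involves coefficients j..j+d; it is
    located at the mean Greville abscissa of those coefficients.
    """
    p = basis.nbasis
    t = basis.knots
    d = basis.degree
    greville = np.array([t[j + 1: j + d + 1].mean() for j in range(p)])
    order = p - n_rows  # 1 for D1 rows, 2 for D2 rows
    pos = np.array([greville[j: j + order + 1].mean() for j in range(n_rows)])
    frac = (pos - basis.lo) / (basis.hi - basis.lo)
    out = []
    for lo_f, hi_f, direction in regions:
        mask = (frac >= lo_f - 1e-12) & (frac <= hi_f + 1e-12)
        out.append((mask, int(direction)))
    return out


def _violation_masks(beta: np.ndarray, basis: BSplineBasis,
                     shapes: ShapeConstraintSpec) -> tuple[np.ndarray, np.ndarray]:
    p = len(beta)
    d1 = np.diff(beta)
    d2 = np.diff(beta, 2)
    d3 = np.diff(beta, 3)
    scale = float(np.abs(beta).max()) + 1.0
    eps = 1e-9 * scale  # ignore numerically-zero violations (mask flicker)
    V1 = np.zeros(p - 1)
    for mask, direction in _region_masks(basis, shapes.monotone, p - 1):
        V1[mask & (direction * d1 < -eps)] = 1.0
    V2 = np.zeros(p - 2)
    # second-derivative trend: change in second differences (third differences)
    # must share the region's sign; a violating change marks both flanking rows
    viol3 = np.zeros(p - 3, dtype=bool)
    for mask, direction in _region_masks(basis, shapes.curvature_trend, p - 3):
        viol3 |= mask & (direction * d3 < -eps)
    V2[:-1][viol3] = 1.0
    V2[1:][viol3] = 1.0
    return V1, V2


def fit_shape_constrained(s, x, nbasis: int = 30, df: float = 25.0,
                          constraint: EqualityConstraint | None = None,
                          shapes: ShapeConstraintSpec | None = None,
                          kappa_factor: float = 100.0,
                          max_iter: int = 50,
                          domain: tuple[float, float] | None = None) -> PSplineModel:
    """P-spline fit with soft shape penalties and optional exact constraints.

    The objective is the penalised sum of squares with a second-difference
    smoothness penalty (lambda solved from ``df``) plus ``kappa = kappa_factor
    * lambda`` times difference penalties restricted, by 0/1 masks, to
    coefficients currently violating the requested monotone / curvature-trend
    pattern.  Masks are recomputed from the current fit until they stabilise.
    """
    s = np.asarray(s, dtype=float)
    x = np.asarray(x, dtype=float)
    base = fit_pspline(s, x, nbasis=nbasis, df=df, domain=domain)
    basis = base.basis
    B = basis.design(s)
    lam = base.lam
    kappa = kappa_factor * lam
    beta = base.beta
    if shapes is None:
        shapes = ShapeConstraintSpec()
    prev = None
    converged = True
    it = 0
    V1_acc = np.zeros(basis.nbasis - 1)
    V2_acc = np.zeros(basis.nbasis - 2)
    for it in range(1, max_iter + 1):
        V1, V2 = _violation_masks(beta, basis, shapes)
        if it > max_iter // 2:
            # limit cycles between near-equivalent mask sets can occur; making
            # the masks cumulative from here guarantees a fixed point
            V1_acc = np.maximum(V1_acc, V1)
            V2_acc = np.maximum(V2_acc, V2)
            V1, V2 = V1_acc, V2_acc
        Gpen = _penalised_gram(basis, B, lam, kappa, V1, V2)
        beta = np.linalg.solve(Gpen, B.T @ x)
        model = PSplineModel(basis, lam, beta, base.df, kappa=kappa)
        if constraint is not None:
            beta = constrain_through_points(model, constraint, Gpen=Gpen)
        key = (V1.tobytes(), V2.tobytes())
        if key == prev:
            break
        prev = key
    else:
        converged = False
    model = PSplineModel(basis, lam, beta, base.df, kappa=kappa,
                         converged=converged, n_iter=it)
    if constraint is not None:
        model.beta_unconstrained = None
    return model
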