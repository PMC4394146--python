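"""P-spline fitting, df calibration, equality constraints, shape penalties."""

import numpy as np
import pytest

from anacurve.pspline import (BSplineBasis, EqualityConstraint,
                              ShapeConstraintSpec, constrain_through_points,
                              difference_matrix, fit_pspline,
                              fit_shape_constrained)


def hat_trace(s, model):
    B = model.basis.design(s)
    P = difference_matrix(model.basis.nbasis, 2)
    P = P.T @ P
    H = B @ np.linalg.solve(B.T @ B + model.lam * P, B.T)
    return np.trace(H)


@pytest.mark.parametrize("df", [6.0, 12.0, 25.0])
def test_df_calibration_matches_hat_trace(df, rng):
    s = np.linspace(0, 10, 120)
    x = np.sin(s) + 0.05 * rng.standard_normal(len(s))
    model = fit_pspline(s, x, nbasis=30, df=df)
    assert abs(hat_trace(s, model) - df) < 0.05


def test_huge_lambda_gives_least_squares_line(rng):
    s = np.linspace(0, 5, 80)
    x = 2.0 * s - 1.0 + 0.3 * rng.standard_normal(len(s))
    model = fit_pspline(s, x, nbasis=20, lam=1e8)
    line = np.polyval(np.polyfit(s, x, 1), s)
    assert np.abs(model(s) - line).max() < 1e-4


def test_zero_lambda_interpolates_when_basis_is_rich(rng):
    s = np.linspace(0, 1, 20)
    x = rng.standard_normal(20)
    model = fit_pspline(s, x, nbasis=20, lam=0.0)
    assert np.abs(model(s) - x).max() < 1e-8


def test_constraint_already_satisfied_leaves_coefficients(rng):
    s = np.linspace(0, 10, 100)
    x = np.cos(s)
    model = fit_pspline(s, x, nbasis=20, df=10)
    con = EqualityConstraint(np.array([3.0, 7.0]),
                             model(np.array([3.0, 7.0])))
    beta_before = model.beta.copy()
    beta_c = constrain_through_points(model, con, s_data=s)
    assert np.abs(beta_c - beta_before).max() < 1e-8


def test_constraint_residual_is_tiny(rng):
    s = np.linspace(0, 10, 100)
    x = np.cos(s) + 0.1 * rng.standard_normal(len(s))
    model = fit_pspline(s, x, nbasis=20, df=10)
    con = EqualityConstraint(np.array([2.0, 8.5]), np.array([0.7, -0.4]))
    constrain_through_points(model, con, s_data=s)
    assert np.abs(model(con.s) - con.values).max() < 1e-8


def kkt_solve(B, lam, P, x, A, c):
    """Independent equality-constrained ridge solve via the KKT system."""
    p = B.shape[1]
    G = B.T @ B + lam * P
    K = np.block([[2 * G, A.T], [A, np.zeros((A.shape[0], A.shape[0]))]])
    rhs = np.concatenate([2 * B.T @ x, c])
    sol = np.linalg.solve(K, rhs)
    return sol[:p]


def test_constrained_fit_matches_qp_oracle(rng):
    for _ in range(20):
        n, nb = 40, 12
        s = np.sort(rng.uniform(0, 1, n))
        x = rng.standard_normal(n)
        model = fit_pspline(s, x, nbasis=nb, df=rng.uniform(4, 9))
        sc = np.sort(rng.uniform(0.1, 0.9, 2))
        con = EqualityConstraint(sc, rng.standard_normal(2))
        A = con.matrix(model.basis)
        P = difference_matrix(nb, 2)
        beta_c = constrain_through_points(model, con, s_data=s)
        beta_kkt = kkt_solve(model.basis.design(s), model.lam, P.T @ P, x, A,
                             con.values)
        assert np.abs(beta_c - beta_kkt).max() < 1e-8


def test_constraint_scaling_linearity(rng):
    s = np.linspace(0, 1, 60)
    x = np.sin(6 * s)
    sc = np.array([0.25, 0.8])
    cvals = np.array([0.5, -0.2])
    out = {}
    for scale in (1.0, 3.5):
        model = fit_pspline(s, scale * x, nbasis=15, df=8)
        constrain_through_points(
            model, EqualityConstraint(sc, scale * cvals), s_data=s)
        out[scale] = model(s)
    assert np.abs(out[3.5] - 3.5 * out[1.0]).max() < 1e-8


def test_shape_penalty_inactive_when_data_already_conform(rng):
    s = np.linspace(0, 1, 80)
    x = np.sin(np.pi * s)  # rises then falls: conforms to the upper-lip shape
    shapes = ShapeConstraintSpec.upper_lip()
    con = EqualityConstraint(np.array([0.0, 1.0]), np.array([0.0, 0.0]))
    constrained = fit_shape_constrained(s, x, nbasis=20, df=12,
                                        constraint=con, shapes=shapes)
    plain = fit_pspline(s, x, nbasis=20, df=12)
    constrain_through_points(plain, con, s_data=s)
    assert constrained.converged
    assert np.abs(constrained(s) - plain(s)).max() < 1e-6


def test_monotone_penalty_represses_artificial_dip(rng):
    s = np.linspace(0, 1, 150)
    x = np.sin(np.pi * s)
    dip = -0.25 * np.exp(-((s - 0.2) ** 2) / (2 * 0.03 ** 2))
    xd = x + dip
    shapes = ShapeConstraintSpec.upper_lip()
    model = fit_shape_constrained(s, xd, nbasis=25, df=20, shapes=shapes)
    fitted = model(np.linspace(0.02, 0.38, 100))
    drops = np.diff(fitted)
    data_range = xd.max() - xd.min()
    assert drops.min() >= -1e-3 * data_range


def test_shape_fit_descends_objective_with_fixed_masks(rng):
    s = np.linspace(0, 1, 100)
    x = np.sin(np.pi * s) - 0.08 * np.exp(-((s - 0.25) ** 2) / 0.005)
    shapes = ShapeConstraintSpec.upper_lip()
    model = fit_shape_constrained(s, x, nbasis=20, df=10, shapes=shapes)
    assert model.converged
    # at the converged masks, the returned beta is the exact minimiser of the
    # full penalised objective; perturbations can only increase it
    from anacurve.pspline import _penalised_gram, _violation_masks

    V1, V2 = _violation_masks(model.beta, model.basis, shapes)
    B = model.basis.design(s)
    G = _penalised_gram(model.basis, B, model.lam, model.kappa, V1, V2)

    def objective(beta):
        return float(beta @ G @ beta - 2 * (B.T @ x) @ beta)

    base = objective(model.beta)
    rng2 = np.random.default_rng(7)
    for _ in range(5):
        assert objective(model.beta + 1e-3 * rng2.standard_normal(len(model.beta))) > base


def test_basis_rejects_degenerate_setup():
    with pytest.raises(ValueError):
        BSplineBasis(0.0, 1.0, 3)
    with pytest.raises(ValueError):
        BSplineBasis(1.0, 1.0, 10)
    with pytest.raises(ValueError):
        fit_pspline(np.linspace(0, 1, 10), np.zeros(10), nbasis=12)  # no df/lam
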