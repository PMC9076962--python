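"""Restricted-cubic-spline basis and spline-logistic survival fits."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from dacpr_audit.splines import (
    RCSBasis,
    SplineLogisticModel,
    default_knots,
    fit_spline_logistic,
    predict_curve,
    rcs_basis,
)


# --- basis construction -----------------------------------------------------

def test_basis_has_k_minus_one_columns():
    for k in (3, 4, 5):
        knots = tuple(np.linspace(0, 300, k))
        X = rcs_basis(np.linspace(0, 300, 50), knots)
        assert X.shape == (50, k - 1)


def test_basis_rejects_bad_knots():
    with pytest.raises(ValueError, match="3 knots"):
        RCSBasis((0.0, 100.0))
    with pytest.raises(ValueError, match="strictly increasing"):
        RCSBasis((0.0, 100.0, 100.0))


def test_below_first_knot_nonlinear_columns_vanish():
    X = rcs_basis(np.array([1.0, 5.0, 9.0]), (10.0, 50.0, 90.0, 130.0))
    assert np.allclose(X[:, 1:], 0.0)
    assert np.allclose(X[:, 0], [1.0, 5.0, 9.0])


def test_middle_knot_value_matches_hand_arithmetic():
    # knots (0, 50, 100): at x = 50 only the first truncated term is active,
    # (50-0)^3 / (100-0)^2 = 12.5
    X = rcs_basis(np.array([50.0]), (0.0, 50.0, 100.0))
    assert X[0, 1] == pytest.approx(12.5)


def _spline_fn(basis, coefs):
    return lambda x: basis.design(np.atleast_1d(x))[:, :] @ coefs


def test_second_derivative_continuous_across_knots():
    basis = RCSBasis((30.0, 90.0, 180.0, 300.0))
    coefs = np.array([0.5, 2.0, -3.0])
    f = _spline_fn(basis, coefs)
    h = 1e-3
    for knot in basis.knots:
        def second(x0):
            return (f(x0 + h) - 2 * f(x0) + f(x0 - h))[0] / h**2

        assert second(knot - 5 * h) == pytest.approx(second(knot + 5 * h), abs=1e-3)


def test_linear_beyond_boundary_knots():
    basis = RCSBasis((30.0, 90.0, 180.0, 300.0))
    coefs = np.array([0.5, 2.0, -3.0])
    f = _spline_fn(basis, coefs)
    for xs in (np.linspace(310, 600, 30), np.linspace(-50, 25, 30)):
        vals = f(xs)
        second_diff = np.diff(vals, 2)
        assert np.allclose(second_diff, 0.0, atol=1e-8)


# --- knot placement ---------------------------------------------------------

def test_default_knots_on_uniform_grid():
    assert default_knots(np.arange(0, 101.0), 4) == (5.0, 35.0, 65.0, 95.0)


def test_default_knots_three_values_degenerate():
    knots = default_knots(np.array([10.0, 20.0, 30.0]), 3)
    assert len(knots) == 3 and knots[0] < knots[1] < knots[2]


def test_default_knots_errors():
    with pytest.raises(ValueError, match="distinct"):
        default_knots(np.array([1.0, 1.0, 1.0, 2.0]), 4)
    with pytest.raises(ValueError, match="collaps|fewer"):
        default_knots(np.array([1.0] * 98 + [2.0, 3.0, 4.0, 5.0]), 5)
    with pytest.raises(ValueError, match="k must be"):
        default_knots(np.arange(100.0), 8)


# --- fitting ----------------------------------------------------------------

def _bernoulli_deviance(y, eta):
    return 2 * np.sum(np.logaddexp(0, eta) - y * eta)


def test_tiny_fit_matches_brute_force_optimizer():
    rng = np.random.default_rng(3)
    x = np.array([20, 45, 70, 95, 130, 170, 220, 280, 350, 430, 520, 600.0])
    y = (rng.random(12) < expit(1.5 - 0.01 * x)).astype(float)
    knots = (45.0, 130.0, 350.0)
    model = fit_spline_logistic(x, y, knots)
    B = rcs_basis(x, knots)

    def objective(beta):
        return _bernoulli_deviance(y, beta[0] + B @ beta[1:])

    oracle = minimize(
        objective,
        np.zeros(3),
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 50000, "maxfev": 50000},
    )
    assert model.deviance == pytest.approx(oracle.fun, abs=1e-6)


def test_fit_is_a_local_likelihood_optimum():
    rng = np.random.default_rng(4)
    x = rng.uniform(0, 600, 300)
    y = (rng.random(300) < expit(0.5 - 0.006 * x)).astype(float)
    knots = default_knots(x, 4)
    model = fit_spline_logistic(x, y, knots)
    B = rcs_basis(x, knots)
    eta = model.coefficients[0] + B @ model.coefficients[1:]
    best = _bernoulli_deviance(y, eta)
    for delta in rng.normal(0, 0.05, size=(20, len(model.coefficients))):
        beta = model.coefficients + delta
        assert _bernoulli_deviance(y, beta[0] + B @ beta[1:]) >= best - 1e-9


def test_parameter_recovery_on_curvature_free_simulation():
    rng = np.random.default_rng(5)
    n = 5000
    intercept, slope = 0.5, -0.008
    x = rng.uniform(0, 600, n)
    y = (rng.random(n) < expit(intercept + slope * x)).astype(float)
    model = fit_spline_logistic(x, y, default_knots(x, 4))
    assert model.converged
    se = np.sqrt(np.diag(model.cov_params))
    # nonlinear terms consistent with zero; intercept and slope recovered
    for j in range(2, len(model.coefficients)):
        assert abs(model.coefficients[j]) < 3 * se[j]
    assert abs(model.coefficients[0] - intercept) < 3 * se[0]
    assert abs(model.coefficients[1] - slope) < 3 * se[1]


def test_constant_outcome_is_an_error():
    x = np.linspace(0, 100, 20)
    with pytest.raises(ValueError, match="constant"):
        fit_spline_logistic(x, np.ones(20), (10.0, 50.0, 90.0))


def test_complete_separation_is_flagged_not_raised():
    x = np.array([1.0, 2, 3, 4, 100, 110, 120, 130])
    y = np.array([1.0, 1, 1, 1, 0, 0, 0, 0])
    model = fit_spline_logistic(x, y, (2.0, 50.0, 120.0))
    assert not model.converged


def test_missing_pairs_are_dropped_with_count():
    x = [10.0, None, 30.0, 40.0, None, 60.0, 70.0, 80.0]
    y = [1, 1, None, 0, 0, 1, 0, 0]
    model = fit_spline_logistic(x, y, (10.0, 40.0, 80.0))
    assert model.n_dropped == 3
    assert model.n_obs == 5


# --- prediction -------------------------------------------------------------

def test_prediction_at_training_points_matches_fit():
    rng = np.random.default_rng(6)
    x = rng.uniform(0, 500, 200)
    y = (rng.random(200) < expit(0.3 - 0.005 * x)).astype(float)
    model = fit_spline_logistic(x, y, default_knots(x, 4))
    xs = np.sort(x[:20])
    curve = predict_curve(model, xs)
    assert np.allclose(curve.p, model.predict(xs))
    assert np.all((curve.p > 0) & (curve.p < 1))


def test_zero_coefficients_predict_one_half():
    basis = RCSBasis((0.0, 100.0, 200.0, 300.0))
    model = SplineLogisticModel(
        basis=basis,
        coefficients=np.zeros(basis.n_columns + 1),
        cov_params=None,
        converged=True,
        n_iter=0,
        deviance=0.0,
        n_obs=0,
        n_dropped=0,
    )
    curve = predict_curve(model, np.linspace(0, 300, 7))
    assert np.allclose(curve.p, 0.5)


def test_monotone_decreasing_truth_gives_decreasing_fit():
    rng = np.random.default_rng(7)
    n = 5000
    x = rng.uniform(0, 600, n)
    y = (rng.random(n) < expit(1.0 - 0.01 * x)).astype(float)
    model = fit_spline_logistic(x, y, default_knots(x, 4))
    inner = np.linspace(model.basis.knots[1], model.basis.knots[-2], 50)
    p = model.predict(inner)
    assert np.all(np.diff(p) < 0)


def test_wald_band_brackets_the_point_estimate():
    rng = np.random.default_rng(8)
    x = rng.uniform(0, 500, 400)
    y = (rng.random(400) < expit(0.2 - 0.004 * x)).astype(float)
    model = fit_spline_logistic(x, y, default_knots(x, 4))
    curve = predict_curve(model, np.linspace(10, 490, 30), conf_level=0.95)
    assert np.all(curve.lower < curve.p) and np.all(curve.p < curve.upper)
    assert np.all((curve.lower > 0) & (curve.upper < 1))


def test_descending_grid_rejected():
    basis = RCSBasis((0.0, 1.0, 2.0))
    model = SplineLogisticModel(
        basis, np.zeros(3), None, True, 0, 0.0, 0, 0
    )
    with pytest.raises(ValueError, match="ascending"):
        predict_curve(model, np.array([3.0, 2.0, 1.0]))
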