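"""Survival probability as a smooth function of delay.

Logistic regression of the 30-day outcome on a restricted cubic spline
(natural spline) of a delay variable, the standard way to display how an
outcome probability varies with a continuous predictor without assuming
linearity on the logit scale.

The basis is Harrell's truncated-power construction: for knots
``t_1 < ... < t_k`` the design has ``k - 1`` columns — the identity term
``x`` plus ``k - 2`` normalized truncated-cubic terms

    C_j(x) = [ (x - t_j)_+^3
               - (x - t_{k-1})_+^3 (t_k - t_j) / (t_k - t_{k-1})
               + (x - t_k)_+^3 (t_{k-1} - t_j) / (t_k - t_{k-1}) ]
             / (t_k - t_1)^2,          j = 1 .. k-2,

which makes the fitted spline linear beyond the boundary knots with
continuous value, slope and curvature everywhere.  The ``(t_k - t_1)^2``
normalization keeps spline coefficients on the scale of the linear term.

Model fitting maximizes the Bernoulli likelihood by iteratively reweighted
least squares (via statsmodels GLM); complete separation or non-convergence
is reported as a flag on the result, never as a crash.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.special import expit
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    DomainWarning,
    PerfectSeparationWarning,
)

__all__ = [
    "RCSBasis",
    "SplineLogisticModel",
    "SurvivalCurve",
    "HARRELL_KNOT_QUANTILES",
    "rcs_basis",
    "default_knots",
    "fit_spline_logistic",
    "predict_curve",
]

#: Harrell's default knot quantiles by knot count
HARRELL_KNOT_QUANTILES: dict[int, tuple[float, ...]] = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
    6: (0.05, 0.23, 0.41, 0.59, 0.77, 0.95),
    7: (0.025, 0.1833, 0.3417, 0.50, 0.6583, 0.8167, 0.975),
}


@dataclass(frozen=True)
class RCSBasis:
    """Knot locations of a restricted cubic spline basis."""

    knots: tuple[float, ...]

    def __post_init__(self):
        knots = tuple(float(t) for t in self.knots)
        if len(knots) < 3:
            raise ValueError(f"need at least 3 knots, got {len(knots)}")
        if any(b <= a for a, b in zip(knots, knots[1:])):
            raise ValueError(f"knots must be strictly increasing: {knots}")
        object.__setattr__(self, "knots", knots)

    @property
    def n_columns(self) -> int:
        """Number of design columns: linear term plus k-2 nonlinear terms."""
        return len(self.knots) - 1

    @property
    def normalization(self) -> float:
        """Harrell's (t_k - t_1)^2 scale factor for the cubic terms."""
        return (self.knots[-1] - self.knots[0]) ** 2

    def design(self, x) -> np.ndarray:
        """Evaluate the basis at ``x``; shape (len(x), k-1), no intercept."""
        x = np.asarray(x, dtype=float)
        t = np.asarray(self.knots)
        k = len(t)
        cols = [x]
        denom = t[k - 1] - t[k - 2]
        for j in range(k - 2):
            cube = (
                np.clip(x - t[j], 0, None) ** 3
                - np.clip(x - t[k - 2], 0, None) ** 3 * (t[k - 1] - t[j]) / denom
                + np.clip(x - t[k - 1], 0, None) ** 3 * (t[k - 2] - t[j]) / denom
            )
            cols.append(cube / self.normalization)
        return np.column_stack(cols)


def rcs_basis(x, knots: Sequence[float]) -> np.ndarray:
    """Design columns of the restricted cubic spline with the given knots."""
    return RCSBasis(tuple(knots)).design(x)


def default_knots(x, k: int = 4) -> tuple[float, ...]:
    """Knot locations at Harrell's default quantiles for ``k`` knots (3-7)."""
    if k not in HARRELL_KNOT_QUANTILES:
        raise ValueError(f"k must be one of {sorted(HARRELL_KNOT_QUANTILES)}, got {k}")
    x = np.asarray(x, dtype=float)
    if np.unique(x).size < k:
        raise ValueError(f"need at least {k} distinct values to place {k} knots")
    knots = np.percentile(x, [100 * q for q in HARRELL_KNOT_QUANTILES[k]])
    if np.unique(knots).size < k:
        raise ValueError(
            "tied data collapse knot quantiles; use fewer knots or explicit knots"
        )
    return tuple(float(t) for t in knots)


@dataclass
class SplineLogisticModel:
    """A fitted spline-logistic survival model.

    ``coefficients`` holds the intercept followed by one coefficient per
    basis column.  ``converged`` is False under complete separation or when
    IRLS hit the iteration cap.
    """

    basis: RCSBasis
    coefficients: np.ndarray
    cov_params: Optional[np.ndarray]
    converged: bool
    n_iter: int
    deviance: float
    n_obs: int
    n_dropped: int

    def linear_predictor(self, x) -> np.ndarray:
        X = self.basis.design(x)
        return self.coefficients[0] + X @ self.coefficients[1:]

    def predict(self, x) -> np.ndarray:
        """Predicted survival probability at delay ``x``."""
        return expit(self.linear_predictor(x))


@dataclass
class SurvivalCurve:
    """Predicted survival probability over a delay grid, with optional band."""

    grid: np.ndarray
    p: np.ndarray
    lower: Optional[np.ndarray] = None
    upper: Optional[np.ndarray] = None

    def to_frame(self):
        import pandas as pd

        data = {"time_s": self.grid, "p": self.p}
        if self.lower is not None:
            data["lower"] = self.lower
            data["upper"] = self.upper
        return pd.DataFrame(data)


def fit_spline_logistic(
    times,
    outcomes,
    knots: Sequence[float],
    *,
    maxiter: int = 100,
    tol: float = 1e-8,
) -> SplineLogisticModel:
    """Fit logit(p) = intercept + spline(time) by IRLS.

    Pairs with a missing time or outcome are dropped (the drop count is kept
    on the result).  Requires at least one event and one non-event after
    dropping.  Complete separation yields a flagged, non-converged model.
    """
    t = np.asarray([np.nan if v is None else float(v) for v in times])
    y = np.asarray(
        [np.nan if v is None else float(bool(v)) for v in outcomes]
    )
    if t.shape != y.shape:
        raise ValueError("times and outcomes differ in length")
    keep = np.isfinite(t) & np.isfinite(y)
    n_dropped = int((~keep).sum())
    t, y = t[keep], y[keep]
    if t.size == 0:
        raise ValueError("no complete (time, outcome) pairs to fit")
    if y.min() == y.max():
        raise ValueError("outcome is constant: need at least one event and one non-event")

    basis = RCSBasis(tuple(knots))
    X = sm.add_constant(basis.design(t), has_constant="add")

    separated = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        result = model.fit(maxiter=maxiter, tol=tol)  # IRLS, deviance criterion
    for w in caught:
        if issubclass(w.category, PerfectSeparationWarning):
            separated = True
        elif issubclass(w.category, (ConvergenceWarning, DomainWarning)):
            separated = separated or "separation" in str(w.message).lower()

    converged = bool(getattr(result, "converged", True)) and not separated
    try:
        cov = np.asarray(result.cov_params())
        if not np.all(np.isfinite(cov)):
            cov = None
    except Exception:  # singular information matrix under separation
        cov = None

    return SplineLogisticModel(
        basis=basis,
        coefficients=np.asarray(result.params, dtype=float),
        cov_params=cov,
        converged=converged,
        n_iter=int(result.fit_history.get("iteration", maxiter)),
        deviance=float(result.deviance),
        n_obs=int(t.size),
        n_dropped=n_dropped,
    )


def predict_curve(
    model: SplineLogisticModel,
    grid,
    *,
    conf_level: Optional[float] = None,
) -> SurvivalCurve:
    """Survival-probability curve on a delay grid, optionally with a Wald band."""
    grid = np.asarray(grid, dtype=float)
    if grid.size and np.any(np.diff(grid) < 0):
        raise ValueError("grid must be ascending")
    eta = model.linear_predictor(grid)
    p = expit(eta)
    lower = upper = None
    if conf_level is not None:
        if model.cov_params is None:
            raise ValueError("no coefficient covariance available for a band")
        from scipy.stats import norm

        X = sm.add_constant(model.basis.design(grid), has_constant="add")
        se = np.sqrt(np.einsum("ij,jk,ik->i", X, model.cov_params, X))
        z = norm.ppf(0.5 + conf_level / 2)
        lower = expit(eta - z * se)
        upper = expit(eta + z * se)
    return SurvivalCurve(grid=grid, p=p, lower=lower, upper=upper)
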