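"""Re-derivation of parameter equations from measurement tables.

Given measured (cochlear angle, value) pairs for a parameter, this module
reproduces the original model-selection pipeline: outlier removal with a
20-80 percentile window, least-squares fits of the candidate families
(polynomials up to fourth order, one- and two-term exponentials, and a
four-parameter Gaussian), and selection of the lowest-RMSE fit.  It also
provides the rotation-alignment search used to orient sections whose
mid-modiolar rotation angle is unknown.

Fitted results serialise to the same JSON dialect as the built-in
equation registry, so re-derived curves can replace the shipped ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .equations import EquationRegistry, ParameterEquation

__all__ = [
    "FitResult",
    "FitError",
    "percentile_filter",
    "fit_family",
    "select_best",
    "fit_parameter",
    "fit_measurement_table",
    "align_rotation",
]

#: Candidate (family, order) pairs evaluated by the full selection.
CANDIDATE_FAMILIES = (
    ("linear", 1),
    ("polynomial", 2),
    ("polynomial", 3),
    ("polynomial", 4),
    ("exponential", 1),
    ("exponential", 2),
    ("gaussian", 1),
)


class FitError(RuntimeError):
    """Fit could not be performed (too few points, degenerate data)."""


@dataclass(frozen=True)
class FitResult:
    """One fitted candidate curve with its goodness of fit."""

    equation: ParameterEquation
    rmse: float
    n_used: int
    n_removed: int
    converged: bool = True

    @property
    def n_parameters(self) -> int:
        return self.equation.n_parameters


def percentile_filter(
    x, y, lo: float = 20.0, hi: float = 80.0, mode: str = "residual"
) -> np.ndarray:
    """Indices of points retained by the 20-80 percentile outlier window.

    ``mode="residual"`` (default): residuals from a preliminary robust
    (Theil-Sen) straight-line fit are computed and points whose residual
    falls outside the [P20, P80] residual window are removed.  A raw
    window on the values themselves (``mode="value"``) is also available,
    but it would delete the legitimate extremes of angle-dependent
    trends.  Bounds are inclusive, so constant residuals retain all
    points.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D arrays")
    if len(x) < 5:
        raise FitError("percentile filter needs at least 5 points")
    if mode == "residual":
        if np.ptp(x) == 0:
            r = y - np.median(y)
        else:
            slope, intercept, *_ = sps.theilslopes(y, x)
            r = y - (slope * x + intercept)
    elif mode == "value":
        r = y
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    p_lo, p_hi = np.percentile(r, [lo, hi])
    keep = np.nonzero((r >= p_lo - 1e-12) & (r <= p_hi + 1e-12))[0]
    if len(keep) < 3:
        raise FitError("fewer than 3 points survive the percentile window")
    return keep


def _gaussian(t, a, b, c, d):
    return a * np.exp(-c * (t - b) ** 2) + d


def _exp1(t, a, b, c):
    return a * np.exp(b * t) + c


def _exp2(t, a, b, c, d, e):
    return a * np.exp(b * t) + c * np.exp(d * t) + e


def _multistart_curve_fit(fn, x, y, p0_list, bounds=None):
    best = None
    ok = False
    for p0 in p0_list:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = optimize.curve_fit(
                    fn, x, y, p0=p0, maxfev=2000,
                    bounds=bounds if bounds is not None else (-np.inf, np.inf),
                )
            r = float(np.sqrt(np.mean((fn(x, *popt) - y) ** 2)))
            if np.isfinite(r) and (best is None or r < best[1]):
                best = (popt, r)
                ok = True
        except (RuntimeError, ValueError):
            continue
    if best is None:
        return None, np.inf, False
    return best[0], best[1], ok


def fit_family(x, y, family: str, order: int = 1, name: str = "param") -> FitResult:
    """Least-squares fit of one candidate family.

    Polynomials are fitted in the centred variable
    ``theta_n = (x - mean(x)) / std(x)`` and carry their centring pair;
    nonlinear families use five seeded starts around moment-based initial
    guesses.  Non-convergence is flagged on the result, never silent.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D arrays")

    def done(eq, yhat, converged=True):
        rmse = float(np.sqrt(np.mean((yhat - y) ** 2)))
        return FitResult(eq, rmse, n_used=len(x), n_removed=0, converged=converged)

    if family == "linear":
        if len(x) < 2:
            raise FitError("linear fit needs >= 2 points")
        m, q = np.polyfit(x, y, 1)
        eq = ParameterEquation(name, "linear", (m, q))
        return done(eq, m * x + q)

    if family == "polynomial":
        if order < 2 or order > 4:
            raise ValueError("polynomial order must be 2..4")
        if len(x) < order + 1:
            raise FitError(f"order-{order} polynomial needs >= {order + 1} points")
        c1 = float(np.mean(x))
        c2 = float(np.std(x)) or 1.0
        tn = (x - c1) / c2
        coeffs = np.polyfit(tn, y, order)
        eq = ParameterEquation(name, "polynomial", tuple(coeffs), centring=(c1, c2))
        return done(eq, np.polyval(coeffs, tn))

    rng = np.random.default_rng(12345)
    span = float(np.ptp(y)) or 1.0
    xspan = float(np.ptp(x)) or 1.0

    if family == "exponential" and order == 1:
        if len(x) < 4:
            raise FitError("one-term exponential needs >= 4 points")
        base = [
            (y[0] - y[-1], -1.0 / xspan, float(np.min(y))),
            (span, -3.0 / xspan, float(np.mean(y))),
            (-span, -3.0 / xspan, float(np.max(y))),
        ]
        starts = base + [
            tuple(np.array(base[0]) * (1 + 0.3 * rng.standard_normal(3)))
            for _ in range(2)
        ]
        popt, rmse, ok = _multistart_curve_fit(_exp1, x, y, starts)
        if popt is None:
            return FitResult(
                ParameterEquation(name, "exponential", (0.0, 0.0, float(np.mean(y)))),
                float(np.sqrt(np.mean((y - np.mean(y)) ** 2))),
                n_used=len(x), n_removed=0, converged=False,
            )
        eq = ParameterEquation(name, "exponential", tuple(popt))
        return done(eq, _exp1(x, *popt), converged=ok)

    if family == "exponential" and order == 2:
        if len(x) < 6:
            raise FitError("two-term exponential needs >= 6 points")
        base = [
            (span, -1.0 / xspan, span / 2, -5.0 / xspan, float(np.min(y))),
            (-span, -1.0 / xspan, span, -0.3 / xspan, float(np.mean(y))),
        ]
        # seed the two-term fit from the one-term solution: nested models
        # then converge quickly instead of wandering
        p1, _, ok1 = _multistart_curve_fit(_exp1, x, y, [
            (y[0] - y[-1], -1.0 / xspan, float(np.min(y))),
            (span, -3.0 / xspan, float(np.mean(y))),
        ])
        starts = list(base)
        if ok1:
            a1, b1, c1 = p1
            starts.insert(0, (a1, b1, 0.1 * a1, 5 * b1, c1))
        starts += [
            tuple(np.array(base[0]) * (1 + 0.3 * rng.standard_normal(5)))
            for _ in range(2)
        ]
        popt, rmse, ok = _multistart_curve_fit(_exp2, x, y, starts)
        if popt is None:
            return FitResult(
                _TwoTermExponential(name, (0.0, 0.0, 0.0, 0.0, float(np.mean(y)))),
                np.inf, n_used=len(x), n_removed=0, converged=False,
            )
        eq = _TwoTermExponential(name, tuple(float(v) for v in popt))
        return done(eq, _exp2(x, *popt), converged=ok)

    if family == "gaussian":
        if len(x) < 5:
            raise FitError("gaussian fit needs >= 5 points")
        # moment-based initialisation: centre near the extremum
        i_ext = int(np.argmax(np.abs(y - np.median(y))))
        d0 = float(np.median(y))
        a0 = float(y[i_ext] - d0) or span
        b0 = float(x[i_ext])
        c0 = 4.0 / xspan**2
        base = [(a0, b0, c0, d0), (a0, b0, c0 / 10, d0), (-a0, b0, c0, d0 + a0)]
        starts = base + [
            (a0 * (1 + 0.3 * rng.standard_normal()),
             b0 + 0.2 * xspan * rng.standard_normal(),
             c0 * float(np.exp(rng.standard_normal())), d0)
            for _ in range(2)
        ]
        bounds = ([-np.inf, -np.inf, 0.0, -np.inf], np.inf)
        popt, rmse, ok = _multistart_curve_fit(_gaussian, x, y, starts, bounds=bounds)
        if popt is None:
            return FitResult(
                ParameterEquation(name, "gaussian", (0.0, 0.0, 0.0, float(np.mean(y)))),
                float(np.sqrt(np.mean((y - np.mean(y)) ** 2))),
                n_used=len(x), n_removed=0, converged=False,
            )
        eq = ParameterEquation(name, "gaussian", tuple(popt))
        return done(eq, _gaussian(x, *popt), converged=ok)

    raise ValueError(f"unknown family {family!r} (order {order})")


class _TwoTermExponential(ParameterEquation):
    """Carrier for the two-term exponential a*e^(bt) + c*e^(dt) + e."""

    def __init__(self, name: str, coefficients: tuple[float, ...]):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "family", "exponential2")
        object.__setattr__(self, "coefficients", tuple(coefficients))
        object.__setattr__(self, "centring", None)

    def __call__(self, theta_deg):
        t = np.asarray(theta_deg, dtype=float)
        a, b, c, d, e = self.coefficients
        out = a * np.exp(b * t) + c * np.exp(d * t) + e
        return out if out.ndim else float(out)


def select_best(fits, tie_tol: float = 1e-8) -> FitResult:
    """Lowest-RMSE fit; near-ties resolved toward fewer parameters.

    Two fits whose RMSE differ by less than ``tie_tol`` are considered
    tied and the one with fewer parameters wins (so exactly-nested
    families at zero noise resolve to the most parsimonious generator).
    """
    fits = [f for f in list(fits)]
    if not fits:
        raise ValueError("select_best needs a non-empty list of fits")
    best = min(fits, key=lambda f: f.rmse)
    tied = [f for f in fits if f.rmse <= best.rmse + tie_tol]
    return min(tied, key=lambda f: (f.n_parameters, f.rmse))


def fit_parameter(
    x,
    y,
    name: str = "param",
    families=CANDIDATE_FAMILIES,
    filter_outliers: bool = True,
) -> FitResult:
    """Full selection pipeline for one parameter.

    Applies the percentile outlier window (when >= 5 points), fits every
    candidate family that has enough points, and returns the lowest-RMSE
    result with the removed-point count attached.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n_total = len(x)
    if filter_outliers and n_total >= 5:
        keep = percentile_filter(x, y)
        x, y = x[keep], y[keep]
    n_removed = n_total - len(x)
    fits = []
    for family, order in families:
        try:
            fits.append(fit_family(x, y, family, order, name=name))
        except FitError:
            continue
    if not fits:
        raise FitError(f"no candidate family could be fitted for {name!r}")
    best = select_best(fits)
    return FitResult(
        best.equation, best.rmse, n_used=len(x), n_removed=n_removed,
        converged=best.converged,
    )


def fit_measurement_table(
    table: pd.DataFrame, families=CANDIDATE_FAMILIES, filter_outliers: bool = True
) -> dict[str, FitResult]:
    """Fit every parameter in a long measurement table.

    Expects columns theta_deg, parameter, value (the dialect written by
    :func:`cochleagen.synth.synthetic_measurement_table`).
    """
    need = {"theta_deg", "parameter", "value"}
    if not need.issubset(table.columns):
        raise ValueError(f"measurement table needs columns {sorted(need)}")
    results = {}
    for pname, grp in table.groupby("parameter"):
        if len(grp) < 3:
            raise FitError(f"parameter {pname!r} has fewer than 3 measurements")
        results[pname] = fit_parameter(
            grp["theta_deg"].values, grp["value"].values, name=str(pname),
            families=families, filter_outliers=filter_outliers,
        )
    return results


def registry_from_fits(fits: dict[str, FitResult]) -> EquationRegistry:
    """Bundle fitted equations into a registry (two-term exponentials kept)."""
    return EquationRegistry([f.equation for f in fits.values()])


def align_rotation(
    measure,
    bounds: tuple[float, float] = (-15.0, 15.0),
    n_grid: int = 61,
    flat_tol: float = 1e-12,
) -> float:
    """Rotation offset (degrees) minimising the lamina-angle linearity residual.

    ``measure(rotation_deg)`` must return the (theta, alpha) measurement
    pairs obtained after rotating the source image by ``rotation_deg``;
    the objective is the straight-line-fit residual of alpha versus
    theta.  A coarse grid search brackets the minimum and golden-section
    (bounded Brent) refines it.  A flat objective returns 0 with a
    warning.
    """

    def objective(r):
        pairs = np.asarray(measure(float(r)), float)
        if pairs.size == 0:
            raise FitError("rotation callback returned no measurements")
        th, al = pairs[:, 0], pairs[:, 1]
        if len(th) < 2 or np.ptp(th) == 0:
            return float(np.var(al))
        coef = np.polyfit(th, al, 1)
        res = al - np.polyval(coef, th)
        return float(np.sqrt(np.mean(res**2)))

    grid = np.linspace(bounds[0], bounds[1], n_grid)
    vals = np.array([objective(r) for r in grid])
    if np.ptp(vals) <= flat_tol:
        warnings.warn("rotation objective is flat; returning 0", stacklevel=2)
        return 0.0
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        objective, bounds=(lo, hi), method="bounded", options={"xatol": 1e-6}
    )
    return float(res.x)
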