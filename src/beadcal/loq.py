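"""Limits of quantification (LOQ) from a fitted standard curve.

Three estimators are provided, each bounding the concentration range in
which inverse prediction is considered reliable; all work on the log10
concentration scale and report the dynamic range as HLOQ - LLOQ.

Derivative
    The bend points of the sigmoid: the extrema of the second derivative
    of the fitted curve, located as the roots of the third derivative.
    For a 4PL they sit symmetrically at ``e +/- log10(2 + sqrt(3))/|b|``.
    Not applicable to the exponential model (its third derivative is
    identically zero).

Interval
    The LLOQ is the concentration where the lower prediction bound of
    the curve crosses the upper confidence bound of the lower-asymptote
    coefficient; the HLOQ symmetrically uses the upper prediction bound
    and the lower confidence bound of the upper asymptote.  Limits are
    statistically distinguishable from the asymptotes.

Coefficient of variation (CV)
    The delta-method standard error SE(x) of the inverse-predicted
    concentration is converted to a natural-scale CV,
    ``CV = sqrt(exp((SE(x) * ln 10)**2) - 1)``, and the LOQs are the
    extreme grid concentrations with CV at or below a cutoff (20% by
    default here; assay protocols often use 20-30%).

Also here: the confidence/prediction bands of the curve and the
delta-method standard error of an inverse-predicted concentration, which
the Interval and CV methods (and sample calibration) build on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import optimize, stats

from .fitting import CurveFit, FitPreconditionError
from .models import LN10, InversionRangeError, curve_derivative, eval_curve, \
    inverse_curve

#: derivative threshold below which inverse prediction is declared degenerate
SLOPE_TOL = 1e-10

#: default grid resolution for CV scans and root bracketing
GRID_SIZE = 1000


@dataclass
class LoqEstimate:
    """LOQ bounds for one fitted curve, on the log10 concentration scale."""

    method: str
    lloq: float = np.nan
    hloq: float = np.nan
    status: str = "ok"               # ok | not-applicable | not-estimable
    message: str = ""
    settings: dict = dc_field(default_factory=dict)

    @property
    def dynamic_range(self) -> float:
        return self.hloq - self.lloq

    @property
    def lloq_natural(self) -> float:
        return 10.0 ** self.lloq

    @property
    def hloq_natural(self) -> float:
        return 10.0 ** self.hloq

    def contains(self, x: float) -> bool:
        return bool(self.status == "ok" and self.lloq <= x <= self.hloq)

    def to_dict(self) -> dict:
        return {"method": self.method, "lloq": self.lloq, "hloq": self.hloq,
                "dynamic_range": self.dynamic_range if self.status == "ok"
                else np.nan,
                "status": self.status, "message": self.message,
                "settings": self.settings}

    @classmethod
    def from_dict(cls, d: dict) -> "LoqEstimate":
        return cls(method=d["method"], lloq=d["lloq"], hloq=d["hloq"],
                   status=d["status"], message=d.get("message", ""),
                   settings=d.get("settings", {}))


def _require_converged(fit: CurveFit):
    if not fit.converged:
        raise FitPreconditionError("LOQ estimation needs a converged fit")


def _search_range(fit: CurveFit, pad_steps: float = 1.0):
    """Fitted x range extended by one dilution step on each side."""
    x = fit.data["x"].to_numpy()
    step = fit.dilution_step if fit.dilution_step else math.log10(2.0)
    return float(x.min() - pad_steps * step), float(x.max() + pad_steps * step)


# ---------------------------------------------------------------------------
# bands

def se_fit(fit: CurveFit, x):
    """Delta-method SE of the fitted mean response at ``x``:
    sqrt(g' Sigma g) over the free parameters."""
    _require_converged(fit)
    g = np.atleast_2d(fit.free_gradient(x))
    var = np.einsum("ij,jk,ik->i", g, fit.cov, g)
    if np.any(var < -1e-10):
        raise np.linalg.LinAlgError(
            "negative delta-method variance: parameter covariance is not "
            "positive semi-definite")
    out = np.sqrt(np.clip(var, 0.0, None))
    return out if np.ndim(x) else float(out[0])


def curve_band(fit: CurveFit, x, level: float = 0.95,
               band: str = "confidence"):
    """Pointwise confidence or prediction band of the curve at ``x``.

    Both use the t distribution with the fit's residual df.  The
    prediction band adds the residual variance ``sigma**2`` to the
    delta-method variance of the mean, so it contains the confidence
    band wherever ``sigma > 0``.
    """
    _require_converged(fit)
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if band not in ("confidence", "prediction"):
        raise ValueError("band must be 'confidence' or 'prediction'")
    yhat = np.asarray(eval_curve(fit.model, x), dtype=float)
    se = np.asarray(se_fit(fit, x), dtype=float)
    if band == "prediction":
        se = np.sqrt(fit.sigma ** 2 + se ** 2)
    tcrit = stats.t.ppf(1 - (1 - level) / 2, fit.df_resid)
    lower, upper = yhat - tcrit * se, yhat + tcrit * se
    if np.ndim(x):
        return lower, upper
    return float(lower), float(upper)


# ---------------------------------------------------------------------------
# derivative method

def loq_derivative(fit: CurveFit) -> LoqEstimate:
    """Bend-point LOQs: roots of the third derivative of the fitted curve.

    Roots are located by sign-change bracketing on a dense grid over the
    extended standard range and polished with Brent's method; the lower
    root is the LLOQ, the upper the HLOQ.
    """
    _require_converged(fit)
    if fit.model_id == "EXP":
        return LoqEstimate("derivative", status="not-applicable",
                           message="exponential curve has no bend points")
    lo, hi = _search_range(fit, pad_steps=2.0)
    # widen until the grid brackets both roots (they may sit outside the
    # sampled dilutions when the curve is shallow)
    for _ in range(6):
        grid = np.linspace(lo, hi, GRID_SIZE)
        d3 = curve_derivative(fit.model, grid, order=3)
        sign = np.sign(d3)
        flips = np.nonzero(np.diff(sign) != 0)[0]
        if len(flips) >= 2:
            break
        lo, hi = lo - (hi - lo), hi + (hi - lo)
    else:
        return LoqEstimate("derivative", status="not-estimable",
                           message="third-derivative roots not bracketed")
    roots = []
    for i in flips:
        roots.append(optimize.brentq(
            lambda t: curve_derivative(fit.model, t, order=3),
            grid[i], grid[i + 1], xtol=1e-12))
    roots = sorted(roots)
    return LoqEstimate("derivative", lloq=roots[0], hloq=roots[-1],
                       settings={"grid_size": GRID_SIZE})


# ---------------------------------------------------------------------------
# interval method

def loq_interval(fit: CurveFit, level: float = 0.95) -> LoqEstimate:
    """Asymptote-separation LOQs from band/coefficient-CI intersections.

    When a boundary has several crossings, the one closest to ``e`` (the
    curve's interior) is kept, giving the more conservative limit.
    Fixed asymptotes (under the constraint background) have point CIs.
    """
    _require_converged(fit)
    if fit.model_id == "EXP":
        return LoqEstimate("interval", status="not-applicable",
                           message="exponential curve has no asymptote "
                                   "coefficients")
    params = fit.model.as_dict()
    c_hat, d_hat = params["c"], params["d"]
    tcrit = stats.t.ppf(1 - (1 - level) / 2, fit.df_resid)

    def coef_ci(name):
        if name not in fit.free_names:   # constrained: CI collapses
            return params[name], params[name]
        i = fit.free_names.index(name)
        se = math.sqrt(fit.cov[i, i])
        if not np.isfinite(se):
            return None
        return params[name] - tcrit * se, params[name] + tcrit * se

    ci_c, ci_d = coef_ci("c"), coef_ci("d")
    if ci_c is None or ci_d is None:
        return LoqEstimate("interval", status="not-estimable",
                           message="asymptote confidence interval not "
                                   "estimable")
    c_upper, d_lower = ci_c[1], ci_d[0]

    lo, hi = _search_range(fit)
    grid = np.linspace(lo, hi, GRID_SIZE)
    pred_lo, pred_hi = curve_band(fit, grid, level=level, band="prediction")
    e_hat = params["e"]

    def crossing(values, target):
        """Root of values - target on the grid, crossing closest to e."""
        diff = values - target
        flips = np.nonzero(np.diff(np.sign(diff)) != 0)[0]
        if len(flips) == 0:
            return None
        best = min(flips, key=lambda i: abs((grid[i] + grid[i + 1]) / 2 - e_hat))
        lo_b, hi_b = grid[best], grid[best + 1]
        f_lo = diff[best]
        f_hi = diff[best + 1]
        if f_lo == 0:
            return float(lo_b)
        if f_hi == 0:
            return float(hi_b)
        # linear interpolation then brentq refinement on the band function
        return float(optimize.brentq(
            lambda t: _band_value(fit, t, level, values is pred_lo) - target,
            lo_b, hi_b, xtol=1e-10))

    increasing = params["b"] < 0
    # lower prediction bound meets upper CI of c; upper bound meets lower
    # CI of d.  Which bound corresponds to low concentration depends on
    # the curve's direction, but the targets do not.
    lloq = crossing(pred_lo, c_upper) if increasing else crossing(pred_hi, d_lower)
    hloq = crossing(pred_hi, d_lower) if increasing else crossing(pred_lo, c_upper)
    if lloq is None or hloq is None or not lloq < hloq:
        return LoqEstimate("interval", status="not-estimable",
                           message="no prediction-band / asymptote-CI "
                                   "crossing in the search range",
                           settings={"level": level})
    return LoqEstimate("interval", lloq=lloq, hloq=hloq,
                       settings={"level": level})


def _band_value(fit: CurveFit, x: float, level: float, lower: bool) -> float:
    lo, hi = curve_band(fit, x, level=level, band="prediction")
    return lo if lower else hi


# ---------------------------------------------------------------------------
# inverse-prediction SE and the CV method

def concentration_se(fit: CurveFit, y: float,
                     include_response_error: bool = False):
    """Inverse-predicted concentration and its delta-method SE.

    Implicit differentiation of ``f(x; theta) = y`` gives
    ``d x / d theta = -g(x) / f'(x)`` with ``g`` the parameter gradient,
    so ``Var(x) = g' Sigma g / f'(x)**2``.  With
    ``include_response_error`` the residual variance propagates through
    ``dx/dy = 1/f'(x)`` as well; the default conditions on the observed
    MFI and carries parameter uncertainty only.

    Returns ``(x_hat, se)``; ``se`` is ``inf`` when the local slope is
    numerically zero (asymptote region).
    """
    _require_converged(fit)
    x_hat = inverse_curve(fit.model, y)
    slope = curve_derivative(fit.model, x_hat, order=1)
    if abs(slope) < SLOPE_TOL:
        return x_hat, math.inf
    g = fit.free_gradient(x_hat)
    var = float(g @ fit.cov @ g) / slope ** 2
    if include_response_error:
        var += fit.sigma ** 2 / slope ** 2
    return x_hat, math.sqrt(max(var, 0.0))


def cv_from_se(se_x) -> float:
    """Natural-scale coefficient of variation implied by a log10-scale SE:
    ``sqrt(exp((se * ln 10)**2) - 1)`` (the lognormal CV identity)."""
    se_x = np.asarray(se_x, dtype=float)
    with np.errstate(over="ignore"):  # huge SE -> CV = inf, legitimately
        out = np.sqrt(np.expm1((se_x * LN10) ** 2))
    return out if out.ndim else float(out)


def loq_cv(fit: CurveFit, cv_cutoff: float = 0.20, grid=None,
           include_response_error: bool = False) -> LoqEstimate:
    """CV-threshold LOQs over a dense concentration grid.

    At each grid concentration the fitted response is inverse-predicted
    back with its delta-method SE, converted to a natural-scale CV; the
    LOQs are the smallest and largest grid x with CV <= cutoff.
    """
    _require_converged(fit)
    if grid is None:
        lo, hi = _search_range(fit)
        grid = np.linspace(lo, hi, GRID_SIZE)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty concentration grid")
    cvs = np.empty_like(grid)
    for i, x in enumerate(grid):
        y = eval_curve(fit.model, x)
        try:
            _, se = concentration_se(fit, y, include_response_error)
        except InversionRangeError:
            se = math.inf
        cvs[i] = cv_from_se(se) if math.isfinite(se) else math.inf
    ok = cvs <= cv_cutoff
    settings = {"cv_cutoff": cv_cutoff, "grid_size": int(grid.size),
                "min_cv": float(np.min(cvs))}
    if not np.any(ok):
        return LoqEstimate("cv", status="not-estimable",
                           message=f"minimum CV {np.min(cvs):.3f} exceeds "
                                   f"cutoff {cv_cutoff}", settings=settings)
    xs = grid[ok]
    return LoqEstimate("cv", lloq=float(xs.min()), hloq=float(xs.max()),
                       settings=settings)


LOQ_METHODS = {"derivative": loq_derivative, "interval": loq_interval,
               "cv": loq_cv}


def estimate_loq(fit: CurveFit, method: str = "derivative", **kwargs):
    """Dispatch to one of the three LOQ estimators by name."""
    try:
        fn = LOQ_METHODS[method]
    except KeyError:
        raise ValueError(f"unknown LOQ method {method!r}; choose from "
                         f"{sorted(LOQ_METHODS)}") from None
    return fn(fit, **kwargs)
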