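"""Dose-response models for bead-assay standard curves.

All models live in doubly log-transformed space: ``x`` is log10 expected
concentration and ``y`` is log10 median fluorescence intensity (MFI).
Three parameterizations are supported:

``LL5``
    Five-parameter log-logistic,
    ``f(x) = c + (d - c) / (1 + 10**(b*(x - e)))**f``,
    with ``b`` the slope around ``e``, ``c``/``d`` the lower/upper
    asymptotes (log10-MFI), ``e`` the log10 concentration giving the
    halfway response, and ``f > 0`` the asymmetry.

``LL4``
    Four-parameter log-logistic; the same expression with the asymmetry
    fixed at ``f = 1``.

``EXP``
    Exponential growth, ``y = y0 * 10**(x*b)`` on the natural MFI scale,
    i.e. the straight line ``a0 + b*x`` on log10 MFI with
    ``a0 = log10(y0)``.  The exponent is read as the product ``x*b``
    (``b`` a multiplicative growth rate per log10-concentration unit);
    this reading is fixed here and made explicit in the parameter name.

Sign convention: with the ``10**(b*(x-e))`` parameterization an
*increasing* sigmoid has ``b < 0`` (the exponential term vanishes as
``x`` grows).  Nothing in this module flips signs behind your back.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

LN10 = np.log(10.0)

#: coefficient order for each model id
PARAM_NAMES = {
    "LL5": ("b", "c", "d", "e", "f"),
    "LL4": ("b", "c", "d", "e"),
    "EXP": ("a0", "b"),
}

MODEL_IDS = tuple(PARAM_NAMES)


class ParameterDomainError(ValueError):
    """Raised when curve parameters violate the model's domain."""


class InversionRangeError(ValueError):
    """Raised when a response lies outside the invertible range.

    ``side`` is ``"below"`` when the response is at or under the lower
    asymptote and ``"above"`` when at or over the upper asymptote.
    """

    def __init__(self, message: str, side: str):
        super().__init__(message)
        self.side = side


@dataclass(frozen=True)
class CurveModel:
    """A dose-response curve: model id plus ordered coefficient vector."""

    model_id: str
    params: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.model_id not in PARAM_NAMES:
            raise ParameterDomainError(f"unknown model id {self.model_id!r}")
        expected = len(PARAM_NAMES[self.model_id])
        params = tuple(float(p) for p in self.params)
        if len(params) != expected:
            raise ParameterDomainError(
                f"{self.model_id} takes {expected} parameters "
                f"{PARAM_NAMES[self.model_id]}, got {len(params)}"
            )
        object.__setattr__(self, "params", params)
        self._validate()

    def _validate(self):
        if self.model_id in ("LL5", "LL4"):
            c, d = self.params[1], self.params[2]
            if not c < d:
                raise ParameterDomainError(
                    f"lower asymptote must lie below the upper one (c={c}, d={d})"
                )
            if self.model_id == "LL5" and self.params[4] <= 0:
                raise ParameterDomainError(
                    f"asymmetry must be positive (f={self.params[4]})"
                )

    @property
    def param_names(self) -> tuple:
        return PARAM_NAMES[self.model_id]

    @property
    def n_params(self) -> int:
        return len(self.params)

    def as_dict(self) -> dict:
        return dict(zip(self.param_names, self.params))


def _ll5_parts(model: CurveModel):
    """Return (b, c, d, e, f) with f = 1 for LL4."""
    if model.model_id == "LL5":
        return model.params
    b, c, d, e = model.params
    return b, c, d, e, 1.0


def eval_curve(model: CurveModel, x):
    """Evaluate the curve at log10 concentration ``x`` -> log10 MFI."""
    x = np.asarray(x, dtype=float)
    if model.model_id == "EXP":
        a0, b = model.params
        out = a0 + b * x
    else:
        b, c, d, e, f = _ll5_parts(model)
        u = np.power(10.0, b * (x - e))
        out = c + (d - c) / np.power(1.0 + u, f)
    return out if out.ndim else float(out)


def inverse_curve(model: CurveModel, y):
    """Map a log10 MFI back to log10 concentration.

    For the logistic models ``y`` must lie strictly between the
    asymptotes; out-of-range values raise :class:`InversionRangeError`
    tagged with which side was violated.
    """
    y = np.asarray(y, dtype=float)
    if model.model_id == "EXP":
        a0, b = model.params
        if b == 0:
            raise ParameterDomainError("EXP curve with zero slope is not invertible")
        out = (y - a0) / b
        return out if out.ndim else float(out)

    b, c, d, e, f = _ll5_parts(model)
    if np.any(y <= c):
        raise InversionRangeError(
            f"response {y} at or below the lower asymptote c={c}", side="below"
        )
    if np.any(y >= d):
        raise InversionRangeError(
            f"response {y} at or above the upper asymptote d={d}", side="above"
        )
    u = np.power((d - c) / (y - c), 1.0 / f) - 1.0
    out = e + np.log10(u) / b
    return out if out.ndim else float(out)


def curve_derivative(model: CurveModel, x, order: int = 1):
    """Analytic derivative of ``eval_curve`` with respect to ``x``.

    Orders 1-3 are supported.  Writing ``u = 10**(b*(x-e))`` and
    ``L = ln 10``, the k-th derivative of ``(1+u)**-f`` follows from the
    chain rule ``d/dx = b*L*u*d/du``; the cubic factor in the third
    derivative is what the derivative-based LOQ method takes roots of.
    """
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    x = np.asarray(x, dtype=float)
    if model.model_id == "EXP":
        _, b = model.params
        out = np.full_like(x, b if order == 1 else 0.0)
        return out if out.ndim else float(out)

    b, c, d, e, f = _ll5_parts(model)
    u = np.power(10.0, b * (x - e))
    bl = b * LN10
    amp = (d - c) * (-f) * u
    if order == 1:
        out = amp * bl * np.power(1.0 + u, -f - 1.0)
    elif order == 2:
        out = amp * bl**2 * np.power(1.0 + u, -f - 2.0) * (1.0 - f * u)
    else:
        poly = 1.0 - (3.0 * f + 1.0) * u + f**2 * u**2
        out = amp * bl**3 * np.power(1.0 + u, -f - 3.0) * poly
    return out if out.ndim else float(out)


def param_gradient(model: CurveModel, x):
    """Gradient of ``eval_curve`` with respect to the coefficient vector.

    Returned with shape ``(n_params,)`` for scalar ``x`` or
    ``(len(x), n_params)`` for vector ``x``, columns in the order of
    :data:`PARAM_NAMES`.  This is the ``g`` of every delta-method
    variance ``g' Sigma g`` used for bands and concentration SEs.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    xv = np.atleast_1d(x)

    if model.model_id == "EXP":
        grad = np.column_stack([np.ones_like(xv), xv])
    else:
        b, c, d, e, f = _ll5_parts(model)
        u = np.power(10.0, b * (xv - e))
        s = np.power(1.0 + u, -f)          # shrink factor in [0, 1]
        inner = (d - c) * (-f) * np.power(1.0 + u, -f - 1.0) * u * LN10
        db = inner * (xv - e)
        dc = 1.0 - s
        dd = s
        de = inner * (-b)
        cols = [db, dc, dd, de]
        if model.model_id == "LL5":
            cols.append((d - c) * s * (-np.log1p(u)))
        grad = np.column_stack(cols)
    return grad[0] if scalar else grad
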