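"""Standard-curve fitting for multiplex bead immunoassay plates.

Standards are long-format well records (plate, well, analyte, sample,
MFI, expected concentration); blanks are the same minus the expected
concentration.  Curves are fit by nonlinear least squares on
``y = log10(MFI)`` against ``x = log10(expected concentration)`` — the
log transform stabilizes the strongly heteroscedastic raw MFIs — trying
a sequence of models (by default LL5, then LL4, then EXP) and keeping
the first that converges.  Four treatments of the blank-control
background are supported:

``ignore``
    Blanks are not used; the left tail of the curve approaches the
    background on its own.
``subtract``
    The geometric mean (GM) of the blanks is subtracted from every
    standard MFI before the log transform; wells driven to zero or below
    are excluded (their log is undefined) and recorded as such.
``include``
    The blank GM is appended as an extra standard point whose expected
    concentration is the smallest standard concentration divided by the
    serial-dilution factor.
``constraint``
    The lower asymptote (``c``, or the intercept ``a0`` for the
    exponential model) is fixed at log10(GM) and removed from the free
    parameter set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .models import (
    PARAM_NAMES,
    CurveModel,
    ParameterDomainError,
    eval_curve,
    param_gradient,
)

BACKGROUND_METHODS = ("ignore", "subtract", "include", "constraint")

#: canonical column names of the tidy long-format tables
STANDARD_COLUMNS = ("plate_id", "well", "analyte", "sample", "mfi", "expected_conc")
BLANK_COLUMNS = ("plate_id", "well", "analyte", "sample", "mfi")

DEFAULT_MODEL_ORDER = ("LL5", "LL4", "EXP")


class FitPreconditionError(ValueError):
    """Too few admissible points (or otherwise unusable input) for a fit."""


# ---------------------------------------------------------------------------
# tables

def normalize_table(df: pd.DataFrame, colmap: Mapping[str, str] | None = None,
                    require_conc: bool = True) -> pd.DataFrame:
    """Rename columns to the canonical schema and add a ``flagged`` column.

    ``colmap`` maps canonical names (``plate_id``, ``well``, ``analyte``,
    ``sample``, ``mfi``, ``expected_conc``) to the actual headers in
    ``df``; omitted keys default to the canonical name itself.
    """
    colmap = dict(colmap or {})
    wanted = list(STANDARD_COLUMNS if require_conc else BLANK_COLUMNS)
    rename = {}
    for canon in wanted:
        actual = colmap.get(canon, canon)
        if actual not in df.columns:
            raise KeyError(f"column {actual!r} (for {canon!r}) not found in table")
        rename[actual] = canon
    out = df.rename(columns=rename)[wanted].copy()
    out["mfi"] = pd.to_numeric(out["mfi"], errors="coerce")
    if require_conc:
        out["expected_conc"] = pd.to_numeric(out["expected_conc"], errors="coerce")
    if "flagged" in df.columns:
        out["flagged"] = df["flagged"].astype(bool).to_numpy()
    else:
        out["flagged"] = False
    return out.reset_index(drop=True)


def read_standards(path, colmap=None) -> pd.DataFrame:
    return normalize_table(pd.read_csv(path), colmap, require_conc=True)


def read_blanks(path, colmap=None) -> pd.DataFrame:
    return normalize_table(pd.read_csv(path), colmap, require_conc=False)


# ---------------------------------------------------------------------------
# background treatment

def geometric_mean(values) -> float:
    """Geometric mean of positive values: exp(mean(log v))."""
    v = np.asarray(list(values) if not hasattr(values, "__array__") else values,
                   dtype=float)
    if v.size == 0:
        raise ValueError("geometric mean of an empty collection is undefined")
    if np.any(~np.isfinite(v)) or np.any(v <= 0):
        raise ValueError("geometric mean requires finite positive values")
    return float(np.exp(np.mean(np.log(v))))


def infer_dilution_factor(expected_conc) -> float:
    """Serial-dilution factor as the median ratio of consecutive distinct
    sorted expected concentrations (2.0 for a 1:2 series)."""
    conc = np.unique(np.asarray(expected_conc, dtype=float))
    if conc.size < 2:
        raise ValueError("need at least two distinct concentrations to infer "
                         "a dilution factor")
    ratios = conc[1:] / conc[:-1]
    return float(np.median(ratios))


def apply_background(std: pd.DataFrame, blanks: pd.DataFrame | None,
                     method: str, dilution_factor: float | None = None):
    """Apply one blank-control treatment to a standards table.

    Returns ``(adjusted_table, descriptor)``.  The adjusted table gains
    an ``exclude_reason`` column (``None`` where usable).  The
    descriptor records the method, the blank GM on the natural MFI scale
    (when blanks were used) and, for ``constraint``, the log10 value at
    which the fitter must pin the lower asymptote.
    """
    if method not in BACKGROUND_METHODS:
        raise ValueError(f"unknown background method {method!r}; "
                         f"choose from {BACKGROUND_METHODS}")
    out = std.copy().reset_index(drop=True)
    out["exclude_reason"] = None

    gm = None
    if method != "ignore":
        if blanks is None or len(blanks) == 0:
            raise ValueError(f"background method {method!r} requires blank wells")
        gm = geometric_mean(blanks["mfi"])

    descriptor = {"method": method, "gm": gm, "constraint_value": None}

    if method == "subtract":
        out["mfi"] = out["mfi"] - gm
        bad = out["mfi"] <= 0
        out.loc[bad, "exclude_reason"] = "nonpositive-after-subtract"
    elif method == "include":
        if dilution_factor is None:
            dilution_factor = infer_dilution_factor(out["expected_conc"])
        ref = out.iloc[0]
        extra = {
            "plate_id": ref["plate_id"], "well": "BKG", "analyte": ref["analyte"],
            "sample": "background", "mfi": gm,
            "expected_conc": float(out["expected_conc"].min()) / dilution_factor,
            "flagged": False, "exclude_reason": None,
        }
        out = pd.concat([out, pd.DataFrame([extra])], ignore_index=True)
    elif method == "constraint":
        descriptor["constraint_value"] = math.log10(gm)

    return out, descriptor


# ---------------------------------------------------------------------------
# fit container

@dataclass
class CurveFit:
    """A fitted (or failed) standard curve with full provenance.

    ``cov`` covers the *free* parameters only; under the ``constraint``
    background the fixed lower asymptote is absent from both ``cov`` and
    ``free_names``.  ``data`` holds the points that entered the
    objective, with fitted values and (standardized) residuals;
    ``excluded`` holds the wells that did not, each with a reason
    (``flagged`` or ``nonpositive-after-subtract``).
    """

    plate_id: str
    analyte: str
    converged: bool
    model_id: str | None
    model: CurveModel | None
    free_names: tuple
    cov: np.ndarray | None
    sigma: float | None
    df_resid: int
    n_used: int
    data: pd.DataFrame
    excluded: pd.DataFrame
    bkg_method: str
    bkg_value: float | None
    constraint_value: float | None
    fallback_log: list = dc_field(default_factory=list)
    dilution_step: float | None = None

    @property
    def rss(self) -> float:
        return float(np.sum(self.data["residual"].to_numpy() ** 2))

    def free_gradient(self, x):
        """Delta-method gradient restricted to the free parameters."""
        g = param_gradient(self.model, x)
        names = PARAM_NAMES[self.model_id]
        idx = [names.index(n) for n in self.free_names]
        return g[..., idx]

    def predict(self, x):
        return eval_curve(self.model, x)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "plate_id": self.plate_id, "analyte": self.analyte,
            "converged": self.converged, "model_id": self.model_id,
            "params": list(self.model.params) if self.model else None,
            "free_names": list(self.free_names),
            "cov": None if self.cov is None else self.cov.tolist(),
            "sigma": self.sigma, "df_resid": self.df_resid,
            "n_used": self.n_used,
            "data": self.data.to_dict(orient="list"),
            "excluded": self.excluded.to_dict(orient="list"),
            "bkg_method": self.bkg_method, "bkg_value": self.bkg_value,
            "constraint_value": self.constraint_value,
            "fallback_log": self.fallback_log,
            "dilution_step": self.dilution_step,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CurveFit":
        model = (CurveModel(d["model_id"], tuple(d["params"]))
                 if d.get("params") else None)
        return cls(
            plate_id=d["plate_id"], analyte=d["analyte"],
            converged=d["converged"], model_id=d["model_id"], model=model,
            free_names=tuple(d["free_names"]),
            cov=None if d["cov"] is None else np.asarray(d["cov"], dtype=float),
            sigma=d["sigma"], df_resid=d["df_resid"], n_used=d["n_used"],
            data=pd.DataFrame(d["data"]), excluded=pd.DataFrame(d["excluded"]),
            bkg_method=d["bkg_method"], bkg_value=d["bkg_value"],
            constraint_value=d["constraint_value"],
            fallback_log=[tuple(t) for t in d["fallback_log"]],
            dilution_step=d.get("dilution_step"),
        )


# ---------------------------------------------------------------------------
# starting values

def _start_values(model_id: str, x: np.ndarray, y: np.ndarray,
                  fixed: Mapping[str, float]) -> dict:
    ylo, yhi = float(np.min(y)), float(np.max(y))
    yrange = max(yhi - ylo, 1e-6)
    c0 = fixed.get("c", ylo - 0.05 * yrange)
    d0 = yhi + 0.05 * yrange
    if model_id == "EXP":
        b0, a0 = np.polyfit(x, y, 1)
        return {"a0": fixed.get("a0", float(a0)), "b": float(b0)}
    # logit linearization: log10((d0-y)/(y-c0)) = b*(x - e)
    c_lin = min(c0, ylo - 0.05 * yrange)
    d_lin = max(d0, yhi + 0.05 * yrange)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.log10((d_lin - y) / (y - c_lin))
    ok = np.isfinite(z)
    if ok.sum() >= 2 and np.ptp(x[ok]) > 0:
        slope, intercept = np.polyfit(x[ok], z[ok], 1)
        b0 = float(slope) if abs(slope) > 1e-8 else -1.0
        e0 = float(-intercept / b0)
    else:
        b0 = -1.0
        e0 = float(x[np.argmin(np.abs(y - (ylo + yhi) / 2))])
    if not np.isfinite(e0) or not (x.min() - 5 < e0 < x.max() + 5):
        e0 = float(np.median(x))
    start = {"b": b0, "c": c0, "d": d0, "e": e0}
    if model_id == "LL5":
        start["f"] = 1.0
    return start


def _fit_one_model(model_id: str, x: np.ndarray, y: np.ndarray,
                   fixed: Mapping[str, float], max_iter: int):
    """Least-squares fit of one model; returns (CurveModel, cov, free_names)
    or raises on non-convergence."""
    names = PARAM_NAMES[model_id]
    free = [n for n in names if n not in fixed]
    n, p = len(x), len(free)
    if n < p + 1:
        raise FitPreconditionError(
            f"{model_id}: need at least {p + 1} points, have {n}")

    start = _start_values(model_id, x, y, fixed)
    theta0 = np.array([start[n_] for n_ in free], dtype=float)

    def assemble(theta):
        vals = dict(fixed)
        vals.update(zip(free, theta))
        return tuple(vals[n_] for n_ in names)

    def resid(theta):
        try:
            m = CurveModel(model_id, assemble(theta))
        except ParameterDomainError:
            return np.full_like(y, 1e6)
        return eval_curve(m, x) - y

    res = optimize.least_squares(resid, theta0, method="lm",
                                 xtol=1e-10, ftol=1e-10, gtol=1e-10,
                                 max_nfev=max_iter * max(p, 1) * 10)
    if not res.success or not np.all(np.isfinite(res.x)):
        raise RuntimeError(f"{model_id}: optimizer did not converge")
    model = CurveModel(model_id, assemble(res.x))  # re-validates the domain

    rss = float(np.sum(res.fun ** 2))
    dof = n - p
    sigma2 = rss / dof if dof > 0 else np.nan
    jtj = res.jac.T @ res.jac
    cov = sigma2 * np.linalg.pinv(jtj)
    cov = (cov + cov.T) / 2  # enforce symmetry against round-off
    if not np.all(np.isfinite(cov)):
        raise RuntimeError(f"{model_id}: singular covariance")
    return model, cov, tuple(free)


def fit_standard_curve(std: pd.DataFrame, blanks: pd.DataFrame | None = None,
                       bkg_method: str = "ignore",
                       model_order: Sequence[str] = DEFAULT_MODEL_ORDER,
                       dilution_factor: float | None = None,
                       max_iter: int = 200) -> CurveFit:
    """Fit one analyte's standard curve with background treatment and
    sequential model fallback.

    ``std`` must contain a single (plate, analyte) group.  Flagged wells
    and wells with nonpositive (possibly background-subtracted) MFI are
    excluded from the objective but preserved with a reason.  The first
    model in ``model_order`` that converges wins; every attempt is
    recorded in ``fallback_log``.  A fit where no model converges is
    returned (not raised) with ``converged=False`` so provenance
    survives.
    """
    keys = std[["plate_id", "analyte"]].drop_duplicates()
    if len(keys) != 1:
        raise ValueError("fit_standard_curve expects a single (plate, analyte) "
                         "group; use fit_plate for full tables")
    plate_id, analyte = keys.iloc[0]["plate_id"], keys.iloc[0]["analyte"]

    if np.any(std["expected_conc"].to_numpy(dtype=float) <= 0):
        raise FitPreconditionError("standard expected concentrations must be "
                                   "positive (log10 must be finite)")

    adj, descriptor = apply_background(std, blanks, bkg_method, dilution_factor)
    adj.loc[adj["flagged"] & adj["exclude_reason"].isna(),
            "exclude_reason"] = "flagged"
    # raw nonpositive MFI cannot be log-transformed regardless of background
    raw_bad = (adj["mfi"] <= 0) & adj["exclude_reason"].isna()
    adj.loc[raw_bad, "exclude_reason"] = "nonpositive-after-subtract" \
        if bkg_method == "subtract" else "nonpositive-mfi"

    used = adj[adj["exclude_reason"].isna()].copy()
    excluded = adj[adj["exclude_reason"].notna()].copy()

    x = np.log10(used["expected_conc"].to_numpy(dtype=float))
    y = np.log10(used["mfi"].to_numpy(dtype=float))

    try:
        dil = (dilution_factor if dilution_factor is not None
               else infer_dilution_factor(std["expected_conc"]))
        dilution_step = math.log10(dil)
    except ValueError:
        dilution_step = None

    fallback_log = []
    model = cov = None
    free_names: tuple = ()
    for model_id in model_order:
        fx = {}
        if descriptor["constraint_value"] is not None:
            fx = {("a0" if model_id == "EXP" else "c"):
                  descriptor["constraint_value"]}
        try:
            model, cov, free_names = _fit_one_model(model_id, x, y, fx, max_iter)
        except (RuntimeError, FitPreconditionError, ParameterDomainError) as err:
            fallback_log.append((model_id, f"failed: {err}"))
            model = None
            continue
        fallback_log.append((model_id, "converged"))
        break

    data = used[["plate_id", "well", "analyte", "sample", "flagged"]].copy()
    data["x"] = x
    data["y"] = y

    if model is None:
        data["fitted"] = np.nan
        data["residual"] = np.nan
        data["std_residual"] = np.nan
        return CurveFit(plate_id=plate_id, analyte=analyte, converged=False,
                        model_id=None, model=None, free_names=(), cov=None,
                        sigma=None, df_resid=0, n_used=len(used), data=data,
                        excluded=excluded, bkg_method=bkg_method,
                        bkg_value=descriptor["gm"],
                        constraint_value=descriptor["constraint_value"],
                        fallback_log=fallback_log, dilution_step=dilution_step)

    fitted = eval_curve(model, x)
    resid = y - fitted
    dof = len(x) - len(free_names)
    sigma = float(np.sqrt(np.sum(resid ** 2) / dof)) if dof > 0 else np.nan
    data["fitted"] = fitted
    data["residual"] = resid
    # an essentially exact fit (sigma at numerical noise level) has no
    # meaningful standardized residuals; report zeros, not 0/0 artifacts
    data["std_residual"] = resid / sigma if sigma > 1e-8 else 0.0

    return CurveFit(plate_id=plate_id, analyte=analyte, converged=True,
                    model_id=model.model_id, model=model,
                    free_names=free_names, cov=cov, sigma=sigma, df_resid=dof,
                    n_used=len(used), data=data, excluded=excluded,
                    bkg_method=bkg_method, bkg_value=descriptor["gm"],
                    constraint_value=descriptor["constraint_value"],
                    fallback_log=fallback_log, dilution_step=dilution_step)


def fit_plate(std: pd.DataFrame, blanks: pd.DataFrame | None = None,
              **kwargs) -> dict:
    """Fit every (plate, analyte) group in a long table.

    Blank wells are matched to each group by plate; blanks whose analyte
    matches the group are preferred when present.
    """
    fits = {}
    for (plate, analyte), grp in std.groupby(["plate_id", "analyte"], sort=True):
        blk = None
        if blanks is not None:
            blk = blanks[blanks["plate_id"] == plate]
            per_analyte = blk[blk["analyte"] == analyte]
            if len(per_analyte):
                blk = per_analyte
        fits[(plate, analyte)] = fit_standard_curve(grp, blk, **kwargs)
    return fits


# ---------------------------------------------------------------------------
# diagnostics

def fit_statistics(fit: CurveFit, grouping=None) -> dict:
    """Goodness-of-fit summary: R², adjusted R², AIC and the lack-of-fit
    (Neill) p-value.

    AIC uses the Gaussian log-likelihood convention with the residual
    variance counted as a parameter:
    ``n*ln(2*pi) + n*ln(RSS/n) + n + 2*(p+1)``.
    """
    if not fit.converged:
        raise FitPreconditionError("fit statistics need a converged fit")
    y = fit.data["y"].to_numpy()
    n = len(y)
    p = len(fit.free_names)
    rss = fit.rss
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        r2 = adj = np.nan
    else:
        r2 = 1.0 - rss / tss
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p)
    if rss <= 0:
        aic = -np.inf
    else:
        aic = n * math.log(2 * math.pi) + n * math.log(rss / n) + n + 2 * (p + 1)
    neill = neill_test(fit, grouping)
    return {"r2": r2, "adjusted_r2": adj, "aic": aic,
            "neill_p": neill["p_value"], "neill_status": neill["status"]}


def neill_test(fit: CurveFit, grouping=None) -> dict:
    """ANOVA-based lack-of-fit test against pure replicate error.

    Points sharing an x value (replicated dilutions) supply the
    pure-error sum of squares; the remainder of the fit's RSS is the
    lack-of-fit component.  ``F = (SSlof/(m-p)) / (SSpe/(n-m))`` with m
    the number of groups and p the number of free parameters, referred
    to an F(m-p, n-m) distribution.  When the grouping is degenerate (no
    replicates, or m outside (p, n)) the result carries an ``undefined``
    status instead of a guess.
    """
    if not fit.converged:
        return {"status": "undefined", "message": "fit did not converge",
                "p_value": np.nan, "F": np.nan}
    x = fit.data["x"].to_numpy()
    y = fit.data["y"].to_numpy()
    groups = np.asarray(grouping) if grouping is not None else x
    n = len(y)
    p = len(fit.free_names)
    uniq, inv, counts = np.unique(groups, return_inverse=True,
                                  return_counts=True)
    m = len(uniq)
    if not (p < m < n):
        return {"status": "undefined",
                "message": f"need p < m < n (p={p}, m={m}, n={n})",
                "p_value": np.nan, "F": np.nan}
    if not np.any(counts >= 2):
        return {"status": "undefined",
                "message": "no replicated x values: pure error unavailable",
                "p_value": np.nan, "F": np.nan}
    group_means = np.bincount(inv, weights=y) / counts
    ss_pe = float(np.sum((y - group_means[inv]) ** 2))
    ss_lof = max(fit.rss - ss_pe, 0.0)
    df_lof, df_pe = m - p, n - m
    if ss_pe <= 0:
        return {"status": "undefined", "message": "zero pure error",
                "p_value": np.nan, "F": np.nan}
    F = (ss_lof / df_lof) / (ss_pe / df_pe)
    pval = float(stats.f.sf(F, df_lof, df_pe))
    return {"status": "ok", "p_value": pval, "F": float(F),
            "df": (df_lof, df_pe)}


def summary_coefficients(fits) -> pd.DataFrame:
    """Coefficient table across fits: estimate, SE, t and two-sided p.

    Accepts a single fit, an iterable of fits, or the dict returned by
    :func:`fit_plate`.  Constrained (fixed) coefficients are not tested;
    fits that failed contribute a status-only row.
    """
    if isinstance(fits, CurveFit):
        fits = [fits]
    elif isinstance(fits, dict):
        fits = list(fits.values())
    rows = []
    for fit in fits:
        base = {"plate_id": fit.plate_id, "analyte": fit.analyte,
                "model": fit.model_id, "bkg_method": fit.bkg_method}
        if not fit.converged:
            rows.append({**base, "status": "fit-failed"})
            continue
        se = np.sqrt(np.diag(fit.cov))
        all_params = fit.model.as_dict()
        for i, name in enumerate(fit.free_names):
            est = all_params[name]
            t = est / se[i] if se[i] > 0 else np.inf
            pval = 2 * stats.t.sf(abs(t), fit.df_resid)
            rows.append({**base, "status": "ok", "coefficient": name,
                         "estimate": est, "se": se[i], "t": t, "p_value": pval})
    return pd.DataFrame(rows)
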