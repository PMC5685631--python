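"""QA/QC for fitted standard curves.

Covers outlier detection on standardized residuals, the flag-and-refit
workflow (flag -> refit without the flagged wells -> both fits kept),
intraclass correlation for operator/run reliability, and a per-analyte
report bundle (figures plus machine-readable tables).

Outlier removal is deliberately not iterated automatically: the
workflow is detect, let the analyst flag, refit once, and report any new
exceedances without acting on them.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import CurveFit, fit_standard_curve, fit_statistics, \
    summary_coefficients
from .loq import LoqEstimate, curve_band

DEFAULT_OUTLIER_CUTOFF = 2.0


def get_outliers(fit: CurveFit, cutoff: float = DEFAULT_OUTLIER_CUTOFF
                 ) -> pd.DataFrame:
    """Wells whose |standardized residual| exceeds ``cutoff``.

    Returns a table with plate, analyte, well, the standardized residual
    and the cutoff used, ordered by (plate, analyte, well).
    """
    if not fit.converged:
        raise ValueError("outlier detection needs a converged fit")
    if cutoff < 0:
        raise ValueError("cutoff must be nonnegative")
    d = fit.data
    mask = d["std_residual"].abs() > cutoff
    out = d.loc[mask, ["plate_id", "analyte", "well", "std_residual"]].copy()
    out["cutoff"] = cutoff
    return out.sort_values(["plate_id", "analyte", "well"]).reset_index(drop=True)


def flag_wells(std: pd.DataFrame, wells) -> pd.DataFrame:
    """Return a copy of the standards table with ``flagged`` set on the
    named wells; unknown wells raise with the full list of offenders."""
    wells = list(wells)
    known = set(std["well"])
    unknown = [w for w in wells if w not in known]
    if unknown:
        raise KeyError(f"wells not present in the table: {unknown}")
    out = std.copy()
    out.loc[out["well"].isin(wells), "flagged"] = True
    return out


def flag_and_refit(std: pd.DataFrame, wells, blanks=None, **fit_kwargs):
    """Flag wells and refit the curve without them.

    Returns ``(flagged_table, new_fit)``; the original table and fit are
    untouched so both stages of the QC trail stay retrievable.
    """
    flagged = flag_wells(std, wells)
    return flagged, fit_standard_curve(flagged, blanks, **fit_kwargs)


# ---------------------------------------------------------------------------
# intraclass correlation

_ICC_CODE = {
    ("oneway", "consistency", "single"): "ICC(1,1)",
    ("oneway", "agreement", "single"): "ICC(1,1)",
    ("twoway", "consistency", "single"): "ICC(C,1)",
    ("twoway", "agreement", "single"): "ICC(A,1)",
    ("oneway", "consistency", "average"): "ICC(1,k)",
    ("oneway", "agreement", "average"): "ICC(1,k)",
    ("twoway", "consistency", "average"): "ICC(C,k)",
    ("twoway", "agreement", "average"): "ICC(A,k)",
}


def intra_icc(wide: pd.DataFrame, model: str = "twoway",
              icc_type: str = "consistency", unit: str = "single",
              confidence: float = 0.95) -> dict:
    """Shrout-Fleiss intraclass correlation from a subjects x raters matrix.

    ``model`` chooses the one- or two-way ANOVA decomposition,
    ``icc_type`` whether rater means are allowed to differ (consistency)
    or penalized (agreement), ``unit`` whether the reliability of a
    single rating or the average over raters is wanted.  Rows with any
    missing value are dropped (complete-case, as ANOVA requires).
    Returns the estimate, its F test and the F-based confidence interval.
    """
    wide = pd.DataFrame(wide).dropna(axis=0, how="any")
    if wide.shape[0] < 2 or wide.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 raters/columns")
    key = (model, icc_type, unit)
    if key not in _ICC_CODE:
        raise ValueError(f"unsupported combination {key}")
    code = _ICC_CODE[key]

    import pingouin as pg  # deferred: pingouin import is slow

    long = wide.reset_index(names="_subject").melt(
        id_vars="_subject", var_name="_rater", value_name="_rating")
    table = pg.intraclass_corr(data=long, targets="_subject",
                               raters="_rater", ratings="_rating")
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    row = table[table["Type"] == code].iloc[0]
    lo, hi = row[ci_col]
    icc = float(row["ICC"])
    status = "ok"
    if icc < 0:
        status = "negative-estimate"
    return {"icc": icc, "type": code, "model": model,
            "icc_type": icc_type, "unit": unit,
            "F": float(row["F"]), "df1": float(row["df1"]),
            "df2": float(row["df2"]), "p_value": float(row["pval"]),
            "ci": (float(lo), float(hi)), "confidence": confidence,
            "n_subjects": int(wide.shape[0]), "n_raters": int(wide.shape[1]),
            "status": status}


# ---------------------------------------------------------------------------
# report bundle

def _curve_figure(fit: CurveFit, level: float, band: str):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.6))
    ax = axes[0]
    d = fit.data
    grid = np.linspace(d["x"].min() - 0.3, d["x"].max() + 0.3, 200)
    ax.plot(grid, fit.predict(grid), "-", color="C0", lw=1.5)
    lo, hi = curve_band(fit, grid, level=level, band=band)
    ax.plot(grid, lo, "--", color="C0", lw=0.8)
    ax.plot(grid, hi, "--", color="C0", lw=0.8)
    ax.plot(d["x"], d["y"], "o", color="k", ms=4)
    flagged = fit.excluded[fit.excluded["exclude_reason"] == "flagged"]
    if len(flagged):
        fx = np.log10(flagged["expected_conc"].to_numpy(dtype=float))
        fy = np.log10(flagged["mfi"].to_numpy(dtype=float))
        ax.plot(fx, fy, "o", mfc="none", mec="k", ms=6)  # empty circles
    if fit.bkg_value:
        ax.axhline(math.log10(fit.bkg_value), color="green", lw=1,
                   label="blank GM")
        ax.legend(fontsize=7)
    ax.set_xlabel("log10 concentration")
    ax.set_ylabel("log10 MFI")
    ax.set_title(f"{fit.analyte} ({fit.model_id}, {fit.bkg_method})",
                 fontsize=9)

    ax = axes[1]
    ax.axhline(0, color="0.6", lw=0.8)
    for cut in (-DEFAULT_OUTLIER_CUTOFF, DEFAULT_OUTLIER_CUTOFF):
        ax.axhline(cut, color="0.6", ls="--", lw=0.8)
    ax.plot(d["fitted"], d["std_residual"], "o", ms=4)
    exceed = d[d["std_residual"].abs() > DEFAULT_OUTLIER_CUTOFF]
    for _, r in exceed.iterrows():
        ax.annotate(r["well"], (r["fitted"], r["std_residual"]), fontsize=7,
                    color="red")
    ax.set_xlabel("fitted log10 MFI")
    ax.set_ylabel("standardized residual")

    ax = axes[2]
    sr = np.sort(d["std_residual"].to_numpy())
    qq = stats.norm.ppf((np.arange(1, len(sr) + 1) - 0.5) / len(sr))
    ax.plot(qq, sr, "o", ms=4)
    lim = [min(qq.min(), sr.min()), max(qq.max(), sr.max())]
    ax.plot(lim, lim, "-", color="0.6", lw=0.8)
    ax.set_xlabel("normal quantile")
    ax.set_ylabel("standardized residual")
    fig.tight_layout()
    return fig


def qc_report(fits, loqs=None, outdir: str | Path = "qc",
              level: float = 0.95, band: str = "confidence",
              cutoff: float = DEFAULT_OUTLIER_CUTOFF) -> dict:
    """Assemble the QA/QC bundle for a set of fits.

    Writes, under ``outdir``: one figure per (plate, analyte) with the
    standard curve (chosen band, blank-GM line, flagged wells as empty
    circles), residual-vs-fitted and normal QQ panels; CSV tables of
    coefficients and outliers; and a JSON summary with fit statistics
    and LOQ estimates.  Returns the summary dict.
    """
    if isinstance(fits, CurveFit):
        fits = {(fits.plate_id, fits.analyte): fits}
    if not fits:
        raise ValueError("qc_report needs at least one fit")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    coef = summary_coefficients(fits)
    coef.to_csv(outdir / "coefficients.csv", index=False)

    all_outliers = []
    summary = {}
    for key, fit in fits.items():
        label = f"{key[0]}_{key[1]}".replace("/", "-")
        entry = {"plate_id": fit.plate_id, "analyte": fit.analyte,
                 "model": fit.model_id, "bkg_method": fit.bkg_method,
                 "converged": fit.converged, "n_used": fit.n_used,
                 "fallback_log": fit.fallback_log}
        if fit.converged:
            entry["statistics"] = {
                k: (None if isinstance(v, float) and not math.isfinite(v)
                    else v)
                for k, v in fit_statistics(fit).items()}
            out = get_outliers(fit, cutoff)
            all_outliers.append(out)
            entry["n_outliers"] = int(len(out))
            fig = _curve_figure(fit, level, band)
            fig.savefig(outdir / f"{label}.png", dpi=110)
            import matplotlib.pyplot as plt
            plt.close(fig)
        if loqs:
            loq = loqs.get(key)
            if loq is not None:
                if isinstance(loq, LoqEstimate):
                    loq = {loq.method: loq}
                entry["loq"] = {m: est.to_dict() for m, est in loq.items()}
        summary[label] = entry

    if all_outliers:
        pd.concat(all_outliers, ignore_index=True).to_csv(
            outdir / "outliers.csv", index=False)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
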