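"""Inverse prediction: convert test-sample MFIs to concentrations.

Each test well's MFI is first moved into the response space of the
plate's fitted curve (mirroring the background treatment the curve was
fit with: ``subtract`` subtracts the blank geometric mean, the other
treatments leave the MFI untouched), then inverted through the curve.
Every calibrated well carries a delta-method SE, the natural-scale CV,
and a status against the chosen LOQ estimate.  Batch calibration never
drops a row: wells that cannot be inverted come back with an explanatory
status instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import CurveFit, FitPreconditionError
from .loq import LoqEstimate, concentration_se, cv_from_se
from .models import InversionRangeError

#: mutually exclusive calibration outcomes
STATUSES = ("quantified", "below-lloq", "above-hloq", "below-curve-range",
            "above-curve-range", "not-invertible", "missing-fit")


@dataclass
class CalibratedSample:
    plate_id: str
    well: str
    analyte: str
    sample: str
    mfi: float
    x_hat: float = np.nan        # log10 concentration
    se_x: float = np.nan
    cv: float = np.nan
    status: str = "not-invertible"

    @property
    def conc(self) -> float:
        """Natural-scale concentration, 10**x_hat."""
        return 10.0 ** self.x_hat if math.isfinite(self.x_hat) else np.nan

    def to_dict(self) -> dict:
        return {"plate_id": self.plate_id, "well": self.well,
                "analyte": self.analyte, "sample": self.sample,
                "mfi": self.mfi, "log10_conc": self.x_hat, "conc": self.conc,
                "se_log10_conc": self.se_x, "cv": self.cv,
                "status": self.status}


def estimate_concentration(fit: CurveFit, loq: LoqEstimate | None,
                           mfi: float, plate_id: str = "", well: str = "",
                           analyte: str = "", sample: str = "",
                           include_response_error: bool = False
                           ) -> CalibratedSample:
    """Calibrate one well against a fitted curve and an LOQ estimate."""
    if not fit.converged:
        raise FitPreconditionError("calibration needs a converged fit")
    if not (mfi > 0 and math.isfinite(mfi)):
        raise ValueError(f"test MFI must be positive and finite, got {mfi}")
    out = CalibratedSample(plate_id=plate_id or fit.plate_id, well=well,
                           analyte=analyte or fit.analyte, sample=sample,
                           mfi=float(mfi))

    adj = mfi - fit.bkg_value if fit.bkg_method == "subtract" else mfi
    if adj <= 0:
        out.status = "not-invertible"
        return out
    y = math.log10(adj)
    try:
        x_hat, se = concentration_se(fit, y, include_response_error)
    except InversionRangeError as err:
        out.status = ("below-curve-range" if err.side == "below"
                      else "above-curve-range")
        return out
    out.x_hat = float(x_hat)
    out.se_x = float(se)
    out.cv = cv_from_se(se) if math.isfinite(se) else math.inf
    if loq is None or loq.status != "ok":
        out.status = "quantified"
    elif x_hat < loq.lloq:
        out.status = "below-lloq"
    elif x_hat > loq.hloq:
        out.status = "above-hloq"
    else:
        out.status = "quantified"
    return out


def batch_calibrate(fits: dict, loqs: dict | None, tests: pd.DataFrame,
                    include_response_error: bool = False) -> pd.DataFrame:
    """Calibrate a long table of test wells against per-(plate, analyte)
    fits and LOQ estimates.

    ``fits`` and ``loqs`` are keyed by ``(plate_id, analyte)`` as
    returned by ``fit_plate``.  One output row per input row, always.
    """
    rows = []
    for _, rec in tests.iterrows():
        key = (rec["plate_id"], rec["analyte"])
        base = {"plate_id": rec["plate_id"], "well": rec["well"],
                "analyte": rec["analyte"], "sample": rec.get("sample", ""),
                "mfi": rec["mfi"], "log10_conc": np.nan, "conc": np.nan,
                "se_log10_conc": np.nan, "cv": np.nan}
        fit = fits.get(key)
        if fit is None or not fit.converged:
            rows.append({**base, "status": "missing-fit"})
            continue
        loq = loqs.get(key) if loqs else None
        try:
            cal = estimate_concentration(
                fit, loq, rec["mfi"], plate_id=rec["plate_id"],
                well=rec["well"], analyte=rec["analyte"],
                sample=rec.get("sample", ""),
                include_response_error=include_response_error)
        except ValueError:
            rows.append({**base, "status": "not-invertible"})
            continue
        rows.append(cal.to_dict())
    columns = ["plate_id", "well", "analyte", "sample", "mfi", "log10_conc",
               "conc", "se_log10_conc", "cv", "status"]
    return pd.DataFrame(rows, columns=columns)
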