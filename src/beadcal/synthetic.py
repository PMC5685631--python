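"""Seeded synthetic plates for testing the calibration workflow.

One plate emulates the standard-curve design of a typical multiplex
bead immunoassay run: 16 serial 1:2 dilutions of a reference sample
with the top (most concentrated) dilution duplicated — 17 designed
wells — plus two blank wells.  True responses follow a 4PL on log10
MFI; Gaussian noise is added on the log10 scale; selected wells can be
turned into outliers (noise SD multiplied, 2x by default) or dropped as
missing.  Four presets mirror the scenarios a real multiplexed panel
produces: a clean full curve, a short curve, a short curve with one
outlier, and a full curve with two outliers.

The generating 4PL parameters and noise SD are fixture choices
documented here (b=-1.2, c=1.1, d=3.2, e=0.9 on log10 scales,
sd=0.05 log10-MFI units), picked to look like a mid-quality cytokine
curve; blank MFIs are drawn lognormal around the lower asymptote.
Everything is reproducible from the single config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .models import CurveModel, eval_curve, inverse_curve

WELLS_96 = [f"{r}{c}" for c in range(1, 13) for r in "ABCDEFGH"]


@dataclass(frozen=True)
class ScenarioConfig:
    """Design of one synthetic plate."""

    b: float = -1.2
    c: float = 1.1
    d: float = 3.2
    e: float = 0.9
    n_dilutions: int = 16
    dilution_factor: float = 2.0
    top_conc: float = 1000.0
    duplicate_top: bool = True
    noise_sd: float = 0.05          # SD of log10-MFI noise
    n_outliers: int = 0
    outlier_sd_multiplier: float = 2.0
    missing: tuple = ()             # designed-point indices left unobserved
    n_blanks: int = 2
    blank_sd: float = 0.05          # lognormal spread of blank MFIs
    n_tests: int = 0
    analyte: str = "Analyte"
    plate_id: str = "plate_01"
    seed: int = 0

    def __post_init__(self):
        n_points = self.n_points
        if any(not 0 <= i < n_points for i in self.missing):
            raise ValueError("missing indices out of the designed range")
        if self.n_outliers > n_points - len(self.missing):
            raise ValueError("more outliers than observable points")
        if self.n_dilutions < 2 or self.dilution_factor <= 1:
            raise ValueError("need >= 2 dilutions with factor > 1")
        if n_points + self.n_blanks + self.n_tests > len(WELLS_96):
            raise ValueError("design exceeds the 96-well plate")

    @property
    def n_points(self) -> int:
        return self.n_dilutions + (1 if self.duplicate_top else 0)

    @property
    def truth(self) -> CurveModel:
        return CurveModel("LL4", (self.b, self.c, self.d, self.e))


def scenario_presets() -> dict:
    """The four canonical plate scenarios (all with two blanks).

    analyte1: all 17 points observed, no outliers.
    analyte2: only 10 points observed (7 missing).
    analyte3: 10 points observed, one of them an outlier.
    analyte4: all 17 points, two outliers.
    """
    base = ScenarioConfig()
    missing7 = tuple(range(10, 17))  # drop the most dilute tail points
    return {
        "analyte1": replace(base, analyte="Analyte1"),
        "analyte2": replace(base, analyte="Analyte2", missing=missing7),
        "analyte3": replace(base, analyte="Analyte3", missing=missing7,
                            n_outliers=1),
        "analyte4": replace(base, analyte="Analyte4", n_outliers=2),
    }


def _outlier_noise(rng: np.random.Generator, sd: float, mult: float) -> float:
    """Noise for a designated outlier well: a draw from the inflated
    distribution N(0, mult*sd) conditioned on exceeding twice that SD in
    magnitude, so a well labelled an outlier is genuinely outlying at
    the conventional two-SD criterion rather than an ordinary draw that
    happens to be small."""
    while True:
        eps = rng.normal(0.0, mult * sd)
        if abs(eps) >= 2.0 * mult * sd:
            return eps


def generate_plate(config: ScenarioConfig, rng: np.random.Generator | None
                   = None) -> dict:
    """Generate one plate: standards, blanks, optional test wells, truth.

    Standards carry expected_conc = top/factor**k with the top dilution
    duplicated first; observed MFI is 10**(LL4(log10 conc) + eps) with
    eps ~ N(0, sd) (outlier wells: sd * multiplier).  Test wells, when
    requested, are drawn at log-uniform concentrations across the
    standard range and perturbed with the same noise.  The returned
    ``truth`` records every generating value, including which wells were
    made outliers.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    model = config.truth

    ks = [0] + list(range(config.n_dilutions)) if config.duplicate_top \
        else list(range(config.n_dilutions))
    conc = config.top_conc / config.dilution_factor ** np.asarray(ks, float)
    observed = [i for i in range(config.n_points) if i not in set(config.missing)]
    outlier_idx = sorted(rng.choice(observed, size=config.n_outliers,
                                    replace=False).tolist()) \
        if config.n_outliers else []

    rows = []
    well_iter = iter(WELLS_96)
    for i in range(config.n_points):
        well = next(well_iter)
        if i not in observed:
            continue
        if i in outlier_idx:
            eps = _outlier_noise(rng, config.noise_sd,
                                 config.outlier_sd_multiplier)
        else:
            eps = rng.normal(0.0, config.noise_sd)
        y = eval_curve(model, np.log10(conc[i])) + eps
        rows.append({"plate_id": config.plate_id, "well": well,
                     "analyte": config.analyte,
                     "sample": f"Standard{1 + ks[i]}", "mfi": 10.0 ** y,
                     "expected_conc": conc[i], "flagged": False})
    standards = pd.DataFrame(rows)

    blank_rows = []
    for j in range(config.n_blanks):
        well = next(well_iter)
        mfi = 10.0 ** (config.c + rng.normal(0.0, config.blank_sd))
        blank_rows.append({"plate_id": config.plate_id, "well": well,
                           "analyte": config.analyte,
                           "sample": f"Background{j}", "mfi": mfi,
                           "flagged": False})
    blanks = pd.DataFrame(blank_rows)

    tests = pd.DataFrame(columns=["plate_id", "well", "analyte", "sample",
                                  "mfi", "true_log10_conc"])
    if config.n_tests:
        lo = np.log10(conc.min())
        hi = np.log10(conc.max())
        xt = rng.uniform(lo, hi, size=config.n_tests)
        trows = []
        for j, x in enumerate(xt):
            well = next(well_iter)
            y = eval_curve(model, x) + rng.normal(0.0, config.noise_sd)
            trows.append({"plate_id": config.plate_id, "well": well,
                          "analyte": config.analyte, "sample": f"S{j + 1}",
                          "mfi": 10.0 ** y, "true_log10_conc": x})
        tests = pd.DataFrame(trows)

    truth = {"model": model, "config": config,
             "outlier_wells": [standards.iloc[
                 [observed.index(i) for i in outlier_idx]]["well"].tolist()][0]
             if outlier_idx else [],
             "outlier_indices": outlier_idx}
    return {"standards": standards, "blanks": blanks, "tests": tests,
            "truth": truth}


def generate_panel(presets: Sequence[str] | None = None, seed: int = 0) -> dict:
    """Generate the four-scenario plate as one multiplexed dataset.

    Returns concatenated standards/blanks across the chosen presets
    (all four by default), each analyte generated from an independent
    substream of ``seed``.
    """
    configs = scenario_presets()
    names = list(presets) if presets else list(configs)
    ss = np.random.SeedSequence(seed).spawn(len(names))
    out = {"standards": [], "blanks": [], "truth": {}}
    for name, sub in zip(names, ss):
        cfg = configs[name]
        plate = generate_plate(cfg, rng=np.random.default_rng(sub))
        out["standards"].append(plate["standards"])
        out["blanks"].append(plate["blanks"])
        out["truth"][name] = plate["truth"]
    out["standards"] = pd.concat(out["standards"], ignore_index=True)
    out["blanks"] = pd.concat(out["blanks"], ignore_index=True)
    return out
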