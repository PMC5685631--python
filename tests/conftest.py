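"""Shared fixtures.

``tests/data/synthetic_xponent_fluorescence.csv`` is a small synthetic
file written by hand in the sectioned layout of an xPONENT 3.1
fluorescence export (metadata header, then ``DataType:``-introduced
blocks); it contains no real assay data.
"""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from beadcal.models import CurveModel, eval_curve
from beadcal.fitting import fit_standard_curve
from beadcal.synthetic import ScenarioConfig, generate_plate, scenario_presets

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def ll4():
    """The reference 4PL of the worked examples: b=-1, c=1, d=3, e=1."""
    return CurveModel("LL4", (-1.0, 1.0, 3.0, 1.0))


@pytest.fixture
def xponent_file():
    return DATA_DIR / "synthetic_xponent_fluorescence.csv"


def make_noiseless_standards(model, n=17, top=1000.0, factor=2.0,
                             plate="p1", analyte="A"):
    """Standards lying exactly on ``model`` at a duplicated-top 1:2 series."""
    ks = [0] + list(range(n - 1))
    conc = np.array([top / factor ** k for k in ks])
    y = eval_curve(model, np.log10(conc))
    return pd.DataFrame({
        "plate_id": plate, "well": [f"A{i + 1}" if i < 12 else f"B{i - 11}"
                                    for i in range(n)],
        "analyte": analyte, "sample": [f"Standard{k + 1}" for k in ks],
        "mfi": 10.0 ** y, "expected_conc": conc, "flagged": False})


@pytest.fixture
def noiseless_standards():
    truth = CurveModel("LL4", (-1.2, 1.1, 3.2, 0.8))
    return truth, make_noiseless_standards(truth)


@pytest.fixture
def noisy_fit():
    """A converged, seeded LL4 fit with nonzero residual scale."""
    plate = generate_plate(ScenarioConfig(seed=3))
    return fit_standard_curve(plate["standards"], plate["blanks"],
                              bkg_method="ignore", model_order=("LL4",))


@pytest.fixture
def analyte1_plate():
    from dataclasses import replace
    cfg = replace(scenario_presets()["analyte1"], seed=11, n_tests=20)
    return generate_plate(cfg)
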