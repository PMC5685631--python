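"""Background treatment, NLS fitting with fallback, fit diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from beadcal.fitting import (CurveFit, FitPreconditionError, apply_background,
                             fit_plate, fit_standard_curve, fit_statistics,
                             geometric_mean, infer_dilution_factor,
                             neill_test, normalize_table,
                             summary_coefficients)
from beadcal.models import CurveModel, eval_curve
from tests.conftest import make_noiseless_standards


def blanks_frame(mfis, plate="p1", analyte="A"):
    return pd.DataFrame({
        "plate_id": plate, "well": [f"H{i + 1}" for i in range(len(mfis))],
        "analyte": analyte, "sample": "Background0", "mfi": mfis,
        "flagged": False})


class TestGeometricMean:
    @pytest.mark.parametrize("values,expected", [
        ((100, 100), 100.0),
        ((50, 200), 100.0),
        ((10, 20, 40), 20.0),
    ])
    def test_known_values(self, values, expected):
        assert geometric_mean(values) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [(), (0.0, 1.0), (-5.0,)])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            geometric_mean(bad)


class TestApplyBackground:
    def test_ignore_is_a_no_op(self, noiseless_standards):
        _, std = noiseless_standards
        out, desc = apply_background(std, blanks_frame([50, 200]), "ignore")
        pd.testing.assert_frame_equal(out.drop(columns="exclude_reason"), std)
        assert desc["gm"] is None

    def test_subtract_excludes_nonpositive(self):
        std = make_noiseless_standards(CurveModel("LL4", (-1, 1, 3, 1)))
        std.loc[len(std) - 1, "mfi"] = 80.0   # below the blank GM of 100
        out, desc = apply_background(std, blanks_frame([50, 200]), "subtract")
        assert desc["gm"] == pytest.approx(100.0)
        last = out.iloc[-1]
        assert last["exclude_reason"] == "nonpositive-after-subtract"
        ok = out["exclude_reason"].isna()
        np.testing.assert_allclose(out.loc[ok, "mfi"],
                                   std.loc[ok.to_numpy(), "mfi"] - 100.0)

    def test_include_appends_blank_point(self, noiseless_standards):
        _, std = noiseless_standards
        std = std.copy()
        std["expected_conc"] = std["expected_conc"] / (
            std["expected_conc"].min() / 0.125)   # min conc exactly 0.125
        out, desc = apply_background(std, blanks_frame([60, 60]), "include",
                                     dilution_factor=2.0)
        assert len(out) == len(std) + 1
        extra = out.iloc[-1]
        assert extra["mfi"] == pytest.approx(60.0)
        assert extra["expected_conc"] == pytest.approx(0.0625)

    def test_constraint_descriptor(self, noiseless_standards):
        _, std = noiseless_standards
        out, desc = apply_background(std, blanks_frame([100, 100]),
                                     "constraint")
        assert desc["constraint_value"] == pytest.approx(2.0)  # log10(100)
        assert len(out) == len(std)

    @pytest.mark.parametrize("method", ["subtract", "include", "constraint"])
    def test_methods_requiring_blanks(self, noiseless_standards, method):
        _, std = noiseless_standards
        with pytest.raises(ValueError):
            apply_background(std, None, method)

    def test_dilution_factor_inference(self):
        conc = [1000 / 2 ** k for k in range(8)]
        assert infer_dilution_factor(conc) == pytest.approx(0.5) or \
            infer_dilution_factor(conc) == pytest.approx(2.0)


class TestFitStandardCurve:
    def test_noiseless_recovery(self, noiseless_standards):
        truth, std = noiseless_standards
        fit = fit_standard_curve(std, bkg_method="ignore",
                                 model_order=("LL4",))
        assert fit.converged
        np.testing.assert_allclose(fit.model.params, truth.params, atol=1e-6)
        assert fit_statistics(fit)["r2"] == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_recovery_by_nesting_ll5(self, noiseless_standards):
        truth, std = noiseless_standards
        fit = fit_standard_curve(std, bkg_method="ignore",
                                 model_order=("LL5",))
        assert fit.converged
        x = np.linspace(-1, 3, 50)
        np.testing.assert_allclose(eval_curve(fit.model, x),
                                   eval_curve(truth, x), atol=1e-5)

    def test_fallback_to_simpler_model(self):
        """Three points cannot support a 4-parameter model; the fit must
        fall through to the exponential and log each attempt."""
        m = CurveModel("EXP", (1.0, 0.8))
        conc = np.array([1.0, 10.0, 100.0])
        std = pd.DataFrame({
            "plate_id": "p1", "well": ["A1", "A2", "A3"], "analyte": "A",
            "sample": "s", "mfi": 10.0 ** eval_curve(m, np.log10(conc)),
            "expected_conc": conc, "flagged": False})
        fit = fit_standard_curve(std, model_order=("LL5", "LL4", "EXP"))
        assert fit.converged and fit.model_id == "EXP"
        attempted = [mid for mid, _ in fit.fallback_log]
        assert attempted == ["LL5", "LL4", "EXP"]
        np.testing.assert_allclose(fit.model.params, m.params, atol=1e-8)

    def test_no_model_converges_returns_failure_with_log(self):
        std = pd.DataFrame({
            "plate_id": "p1", "well": ["A1", "A2"], "analyte": "A",
            "sample": "s", "mfi": [10.0, 100.0],
            "expected_conc": [1.0, 10.0], "flagged": False})
        fit = fit_standard_curve(std, model_order=("LL5", "LL4"))
        assert not fit.converged
        assert len(fit.fallback_log) == 2
        with pytest.raises(FitPreconditionError):
            fit_statistics(fit)

    def test_subtract_equivalence(self, analyte1_plate):
        """Fitting with subtract equals fitting the manually shifted
        table with ignore: identical optimizer input, identical fit."""
        std, blk = analyte1_plate["standards"], analyte1_plate["blanks"]
        fit_sub = fit_standard_curve(std, blk, bkg_method="subtract",
                                     model_order=("LL4",))
        gm = geometric_mean(blk["mfi"])
        shifted = std.copy()
        shifted["mfi"] = shifted["mfi"] - gm
        shifted = shifted[shifted["mfi"] > 0]
        fit_ign = fit_standard_curve(shifted, bkg_method="ignore",
                                     model_order=("LL4",))
        assert fit_sub.model.params == fit_ign.model.params
        np.testing.assert_array_equal(fit_sub.cov, fit_ign.cov)

    def test_constraint_removes_parameter(self, analyte1_plate):
        std, blk = analyte1_plate["standards"], analyte1_plate["blanks"]
        fit = fit_standard_curve(std, blk, bkg_method="constraint",
                                 model_order=("LL4",))
        assert fit.converged
        assert fit.free_names == ("b", "d", "e")
        assert fit.cov.shape == (3, 3)
        assert fit.model.as_dict()["c"] == pytest.approx(
            math.log10(geometric_mean(blk["mfi"])))

    def test_flagged_points_leave_objective(self, analyte1_plate):
        std = analyte1_plate["standards"].copy()
        std.loc[std.index[:2], "flagged"] = True
        fit = fit_standard_curve(std, bkg_method="ignore",
                                 model_order=("LL4",))
        assert fit.n_used == len(std) - 2
        assert set(fit.excluded["exclude_reason"]) == {"flagged"}

    def test_nonpositive_concentration_rejected(self):
        std = pd.DataFrame({
            "plate_id": "p", "well": ["A1", "A2"], "analyte": "A",
            "sample": "s", "mfi": [10.0, 20.0],
            "expected_conc": [0.0, 1.0], "flagged": False})
        with pytest.raises(FitPreconditionError):
            fit_standard_curve(std)

    def test_parameter_recovery_against_reported_se(self):
        """Bias of each 4PL coefficient over seeded replicates stays
        below twice its mean reported SE (the fit is calibrated)."""
        from dataclasses import replace
        from beadcal.synthetic import generate_plate, scenario_presets
        cfg = scenario_presets()["analyte1"]
        truth = np.array([cfg.b, cfg.c, cfg.d, cfg.e])
        biases, ses = [], []
        for s in range(60):
            plate = generate_plate(replace(cfg, seed=5000 + s))
            fit = fit_standard_curve(plate["standards"], bkg_method="ignore",
                                     model_order=("LL4",))
            biases.append(np.array(fit.model.params) - truth)
            ses.append(np.sqrt(np.diag(fit.cov)))
        mean_abs_bias = np.abs(np.array(biases)).mean(axis=0)
        mean_se = np.array(ses).mean(axis=0)
        assert np.all(mean_abs_bias < 2 * mean_se)


class TestFitStatistics:
    def test_aic_formula_oracle(self):
        """AIC of a tiny exponential (linear in log space) fit equals a
        direct independent evaluation of the Gaussian AIC."""
        conc = np.array([1.0, 3.0, 10.0, 30.0, 100.0])
        x = np.log10(conc)
        rng = np.random.default_rng(2)
        y = 1.0 + 0.8 * x + rng.normal(0, 0.02, 5)
        std = pd.DataFrame({
            "plate_id": "p", "well": [f"A{i}" for i in range(5)],
            "analyte": "A", "sample": "s", "mfi": 10.0 ** y,
            "expected_conc": conc, "flagged": False})
        fit = fit_standard_curve(std, model_order=("EXP",))
        # independent: ordinary least squares slope/intercept and RSS
        X = np.column_stack([np.ones(5), x])
        beta, rss_arr, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(rss_arr[0])
        n, p = 5, 2
        expected_aic = n * math.log(2 * math.pi) + n * math.log(rss / n) \
            + n + 2 * (p + 1)
        assert fit_statistics(fit)["aic"] == pytest.approx(expected_aic,
                                                           rel=1e-6)

    def test_perfect_fit_r2(self, noiseless_standards):
        _, std = noiseless_standards
        fit = fit_standard_curve(std, model_order=("LL4",))
        st_ = fit_statistics(fit)
        assert st_["r2"] == pytest.approx(1.0, abs=1e-10)


class TestNeill:
    def test_no_replicates_is_undefined(self):
        m = CurveModel("LL4", (-1.2, 1.0, 3.0, 1.0))
        conc = 1000 / 2.0 ** np.arange(8)
        rng = np.random.default_rng(0)
        y = eval_curve(m, np.log10(conc)) + rng.normal(0, 0.03, 8)
        std = pd.DataFrame({
            "plate_id": "p", "well": [f"A{i}" for i in range(8)],
            "analyte": "A", "sample": "s", "mfi": 10.0 ** y,
            "expected_conc": conc, "flagged": False})
        fit = fit_standard_curve(std, model_order=("LL4",))
        assert neill_test(fit)["status"] == "undefined"

    def test_detects_systematic_departure(self):
        """A sinusoidal bump the 4PL cannot absorb must be flagged as
        lack of fit when every dilution is duplicated."""
        m = CurveModel("LL4", (-1.2, 1.1, 3.2, 0.9))
        xs = np.repeat(np.log10(1000 / 2.0 ** np.arange(17)), 2)
        rng = np.random.default_rng(8)
        rejected = 0
        for _ in range(40):
            y = eval_curve(m, xs) + 0.08 * np.sin(2.5 * xs) \
                + rng.normal(0, 0.03, xs.size)
            std = pd.DataFrame({
                "plate_id": "p", "well": [f"W{i}" for i in range(xs.size)],
                "analyte": "A", "sample": "s", "mfi": 10.0 ** y,
                "expected_conc": 10.0 ** xs, "flagged": False})
            fit = fit_standard_curve(std, model_order=("LL4",))
            if neill_test(fit)["p_value"] < 0.05:
                rejected += 1
        assert rejected >= 36  # >= 90% power


class TestSummaryCoefficients:
    def test_t_and_p_oracle(self, noisy_fit):
        tab = summary_coefficients(noisy_fit)
        row = tab.iloc[0]
        assert row["t"] == pytest.approx(row["estimate"] / row["se"])
        assert row["p_value"] == pytest.approx(
            2 * stats.t.sf(abs(row["t"]), noisy_fit.df_resid))

    def test_reference_t_distribution_value(self):
        """estimate 1.0, SE 0.5, df 10 -> t = 2, two-sided p ~ 0.0734
        (frozen from scipy's t distribution)."""
        assert 2 * stats.t.sf(2.0, 10) == pytest.approx(0.07339, abs=2e-5)

    def test_constrained_coefficient_absent(self, analyte1_plate):
        std, blk = analyte1_plate["standards"], analyte1_plate["blanks"]
        fit = fit_standard_curve(std, blk, bkg_method="constraint",
                                 model_order=("LL4",))
        tab = summary_coefficients(fit)
        assert "c" not in set(tab["coefficient"])

    def test_failed_fit_status_row(self):
        std = pd.DataFrame({
            "plate_id": "p1", "well": ["A1", "A2"], "analyte": "A",
            "sample": "s", "mfi": [10.0, 100.0],
            "expected_conc": [1.0, 10.0], "flagged": False})
        fit = fit_standard_curve(std, model_order=("LL4",))
        tab = summary_coefficients(fit)
        assert list(tab["status"]) == ["fit-failed"]
        assert "estimate" not in tab.columns or tab["estimate"].isna().all()


class TestTables:
    def test_column_mapping(self):
        df = pd.DataFrame({"plate": ["p"], "pos": ["A1"], "prot": ["IL6"],
                           "id": ["s"], "MFI": [100], "conc": [5.0]})
        out = normalize_table(df, {"plate_id": "plate", "well": "pos",
                                   "analyte": "prot", "sample": "id",
                                   "mfi": "MFI", "expected_conc": "conc"})
        assert list(out.columns) == ["plate_id", "well", "analyte", "sample",
                                     "mfi", "expected_conc", "flagged"]

    def test_fit_plate_groups(self, analyte1_plate):
        std = analyte1_plate["standards"]
        two = pd.concat([std, std.assign(analyte="Other")], ignore_index=True)
        fits = fit_plate(two, model_order=("LL4",))
        assert set(fits) == {("plate_01", "Analyte1"), ("plate_01", "Other")}
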