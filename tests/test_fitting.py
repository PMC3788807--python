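"""Calibration and kinetic-model fitting, BIC and model selection."""

import numpy as np
import pandas as pd
import pytest

from aslkin.fitting import (
    InversionRecoveryModel,
    SingleStageModel,
    TwoStageModel,
    bic,
    compute_M0b,
    fit_inversion_recovery,
    fit_single_stage,
    fit_two_stage,
    select_model,
)
from aslkin.kinetics import (
    AcquisitionConstants,
    SignalCurve,
    SingleStageParams,
    TwoStageParams,
    single_stage_signal,
    two_stage_signal,
)
from aslkin.simulation import SimulationSpec, add_noise, generate_fpc_series, ir_forward


class TestBIC:
    @pytest.mark.parametrize(
        "rss, n, k, expected",
        [
            (1.0, 12, 2, 12 * np.log(1 / 12) + 2 * np.log(12)),  # ~ -24.85
            (1.0, 12, 5, 12 * np.log(1 / 12) + 5 * np.log(12)),  # ~ -17.39
        ],
    )
    def test_formula(self, rss, n, k, expected):
        assert bic(rss, n, k) == pytest.approx(expected)

    def test_reference_values(self):
        assert bic(1.0, 12, 2) == pytest.approx(-24.85, abs=0.005)
        assert bic(1.0, 12, 5) == pytest.approx(-17.39, abs=0.005)

    def test_parameter_penalty_orders_equal_rss(self):
        assert bic(0.5, 12, 2) < bic(0.5, 12, 5)

    def test_perfect_fit_sentinel(self):
        with pytest.warns(RuntimeWarning):
            assert bic(0.0, 12, 2) == -np.inf

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bic(-1.0, 12, 2)
        with pytest.raises(ValueError):
            bic(1.0, 0, 2)


class TestCalibration:
    def test_compute_m0b(self):
        assert compute_M0b(900.0, 0.9) == pytest.approx(1000.0)
        assert compute_M0b(0.0, 0.9) == 0.0
        assert compute_M0b(1.0, 1.0) == 1.0
        with pytest.raises(ValueError):
            compute_M0b(900.0, 0.0)

    @pytest.mark.parametrize("t1t, m0t", [(1.1, 1000.0), (2.0, 500.0)])
    def test_ir_recovery_noiseless(self, t1t, m0t):
        ti = np.array([0.2, 0.6, 1.4, 2.4])
        fit = fit_inversion_recovery(ir_forward(ti, t1t, m0t), ti=ti)
        assert fit.T1t == pytest.approx(t1t, rel=1e-3)
        assert fit.M0t == pytest.approx(m0t, rel=1e-3)

    def test_all_zero_signal_flagged(self):
        fit = fit_inversion_recovery(np.zeros(4))
        assert not fit.converged

    def test_signed_form_option(self):
        ti = np.array([0.2, 0.6, 1.4, 2.4])
        signed = 500.0 * (1 - 2 * np.exp(-ti / 1.5))
        fit = InversionRecoveryModel(signed, ti=ti, magnitude=False).fit()
        assert fit.T1t == pytest.approx(1.5, rel=1e-3)


class TestSingleStageFit:
    def test_noiseless_self_consistency(self):
        truth = SingleStageParams(BAT=0.7, CBF=60.0, T1t=1.1)
        curve = single_stage_signal(truth, 1.0, AcquisitionConstants())
        res = fit_single_stage(curve, 1.0, 1.1)
        assert res.params["BAT"] == pytest.approx(0.7, rel=0.01)
        assert res.params["CBF"] == pytest.approx(60.0, rel=0.01)
        assert res.k == 2

    def test_all_zero_curve_drives_cbf_to_zero(self):
        curve = SignalCurve(ti=np.arange(0.2, 2.5, 0.2), dM=np.zeros(12))
        res = fit_single_stage(curve, 1.0, 1.1)
        assert res.params["CBF"] < 0.5

    def test_biphasic_curve_underestimates_cbf(self):
        """The single-stage fit to a biphasic curve goes wide and flat: CBF < truth."""
        curve = generate_fpc_series(SimulationSpec())[0.5]
        res = fit_single_stage(curve, 1.0, 1.1)
        assert res.params["CBF"] < 50.0

    def test_nonfinite_data_rejected(self):
        with pytest.raises(ValueError):
            SingleStageModel(np.full(12, np.nan))


class TestTwoStageFit:
    def test_noiseless_parameter_recovery(self):
        truth = TwoStageParams(BAT=0.1, CBF=50.0, pcTT=0.9, f_pc=0.4, BAT_c=0.9, T1t=1.1)
        curve = two_stage_signal(truth, 1.0, AcquisitionConstants())
        res = fit_two_stage(curve, 1.0, 1.1)
        for name in res.params.index:
            assert res.params[name] == pytest.approx(getattr(truth, name), rel=0.05)
        assert res.k == 5

    def test_fpc_zero_ground_truth_recovered_at_boundary(self):
        truth = TwoStageParams(BAT=0.3, CBF=50.0, pcTT=0.9, f_pc=0.0, BAT_c=0.9, T1t=1.1)
        curve = two_stage_signal(truth, 1.0, AcquisitionConstants())
        res = fit_two_stage(curve, 1.0, 1.1)
        assert res.params["f_pc"] < 0.05

    def test_all_zero_curve_drives_cbf_to_zero(self):
        curve = SignalCurve(ti=np.arange(0.2, 2.5, 0.2), dM=np.zeros(12))
        res = fit_two_stage(curve, 1.0, 1.1)
        assert res.params["CBF"] < 0.5

    def test_two_stage_rss_never_worse_than_single(self):
        """The two-stage family effectively nests the single-stage fit."""
        spec = SimulationSpec()
        curves = generate_fpc_series(spec)
        for f in (0.0, 0.3, 0.7):
            c = curves[f]
            rs = fit_single_stage(c, 1.0, 1.1)
            rt = fit_two_stage(c, 1.0, 1.1)
            assert rt.rss <= rs.rss + 1e-9 * float(c.dM @ c.dM)

    def test_fit_is_deterministic(self):
        c = add_noise(generate_fpc_series(SimulationSpec())[0.5], 0.0003, seed=42)
        r1 = fit_two_stage(c, 1.0, 1.1)
        r2 = fit_two_stage(c, 1.0, 1.1)
        assert np.array_equal(r1.params.to_numpy(), r2.params.to_numpy())
        assert r1.rss == r2.rss


class TestModelSelection:
    def test_lower_bic_wins_and_tie_goes_to_single(self):
        class Stub:
            def __init__(self, b):
                self.bic = b

        assert select_model(Stub(-24.85), Stub(-17.39)) == "single"
        assert select_model(Stub(-17.39), Stub(-24.85)) == "two"
        assert select_model(Stub(-20.0), Stub(-20.0)) == "single"
        assert select_model(Stub(-np.inf), Stub(-np.inf)) == "single"

    def test_biphasic_curve_prefers_two_stage(self):
        c = generate_fpc_series(SimulationSpec())[0.5]
        rs = fit_single_stage(c, 1.0, 1.1)
        rt = fit_two_stage(c, 1.0, 1.1)
        assert select_model(rs, rt) == "two"


class TestResultsAPI:
    def test_from_dataframe_and_summary(self):
        curve = generate_fpc_series(SimulationSpec())[0.3]
        df = pd.DataFrame({"TI": curve.ti, "dM": curve.dM})
        res = SingleStageModel.from_dataframe(df, m0b=1.0, t1t=1.1).fit()
        text = res.summary()
        assert "BAT" in text and "CBF" in text and "BIC" in text
        assert res.fittedvalues.shape == curve.dM.shape
        assert np.allclose(res.resid, curve.dM - res.fittedvalues)
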