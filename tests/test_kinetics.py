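"""Closed-form kinetic signals: examples, oracle equivalence, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aslkin.kinetics import (
    AcquisitionConstants,
    SingleStageParams,
    TwoStageParams,
    delivery_function,
    pre_capillary_dm,
    single_stage_dm,
    single_stage_signal,
    two_stage_dm,
    two_stage_signal,
)

from _oracles import numeric_single_stage, numeric_two_stage

C_SHORT = AcquisitionConstants(tau=0.4)
C = AcquisitionConstants()
TI = np.asarray(C.ti_grid)


def relerr(a, b):
    scale = max(np.max(np.abs(b)), 1e-12)
    return np.max(np.abs(a - b) / np.maximum(np.abs(b), 1e-9 * scale))


class TestDeliveryFunction:
    @pytest.mark.parametrize(
        "t, expected",
        [
            (0.05, 0.0),  # before arrival
            (0.3, np.exp(-0.3 / 1.3)),  # inside the bolus window
            (0.6, 0.0),  # after bolus end BAT + tau = 0.5
        ],
    )
    def test_boxcar_with_t1b_decay(self, t, expected):
        assert delivery_function(t, 0.1, C_SHORT) == pytest.approx(expected, abs=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            delivery_function(-0.1, 0.1, C_SHORT)

    def test_scales_with_alpha(self):
        half = AcquisitionConstants(alpha=0.5, tau=0.4)
        assert delivery_function(0.3, 0.1, half) == pytest.approx(
            0.5 * delivery_function(0.3, 0.1, C_SHORT)
        )


class TestInvariantsAndDegeneracies:
    def test_zero_cbf_gives_zero_signal(self):
        curve = single_stage_signal(SingleStageParams(0.1, 0.0, 1.1), 1.0, C)
        assert np.all(curve.dM == 0)

    def test_zero_alpha_gives_zero_signal(self):
        c0 = AcquisitionConstants(alpha=0.0)
        curve = single_stage_signal(SingleStageParams(0.1, 50.0, 1.1), 1.0, c0)
        assert np.all(curve.dM == 0)

    def test_linear_in_m0b_and_alpha(self):
        p = SingleStageParams(0.3, 60.0, 1.1)
        base = single_stage_signal(p, 1.0, C).dM
        assert np.allclose(single_stage_signal(p, 3.5, C).dM, 3.5 * base)
        c_half = AcquisitionConstants(alpha=0.5)
        assert np.allclose(single_stage_signal(p, 1.0, c_half).dM, 0.5 * base)

    def test_signal_vanishes_at_long_times(self):
        t_late = np.array([20.0, 40.0])
        assert np.all(single_stage_dm(t_late, 0.3, 60.0, 1.1, 1.0, C) < 1e-8)
        assert np.all(
            two_stage_dm(t_late, 0.1, 60.0, 0.9, 0.5, 0.9, 1.1, 1.0, C) < 1e-8
        )

    def test_low_flow_limit_linear_in_cbf(self):
        # for CBF*t/lambda -> 0 the residue is ~1 and dM is ~ proportional to f
        lo = single_stage_dm(TI, 0.3, 0.1, 1.1, 1.0, C)
        hi = single_stage_dm(TI, 0.3, 0.2, 1.1, 1.0, C)
        assert np.allclose(hi, 2.0 * lo, rtol=5e-4)

    def test_two_stage_weight_degeneracies(self):
        # f_pc = 0: identical to the single-stage signal with BAT := BAT_c
        p0 = TwoStageParams(BAT=0.2, CBF=50, pcTT=0.9, f_pc=0.0, BAT_c=0.9, T1t=1.1)
        assert np.allclose(
            two_stage_signal(p0, 1.0, C).dM,
            single_stage_signal(SingleStageParams(0.9, 50, 1.1), 1.0, C).dM,
        )
        # f_pc = 1: pure pre-capillary component, no dependence on BAT_c or T1t
        a = two_stage_dm(TI, 0.2, 50, 0.9, 1.0, 0.5, 1.1, 1.0, C)
        b = two_stage_dm(TI, 0.2, 50, 0.9, 1.0, 1.4, 0.6, 1.0, C)
        assert np.array_equal(a, b)
        assert np.allclose(a, pre_capillary_dm(TI, 0.2, 50, 0.9, 1.0, C))

    def test_two_stage_linear_in_mixing_weight(self):
        args = dict(BAT=0.2, CBF=50.0, pcTT=0.9, BAT_c=0.9, T1t=1.1)
        lo = two_stage_dm(TI, f_pc=0.0, M0b=1.0, constants=C, **args)
        hi = two_stage_dm(TI, f_pc=1.0, M0b=1.0, constants=C, **args)
        for w in (0.25, 0.5, 0.8):
            mid = two_stage_dm(TI, f_pc=w, M0b=1.0, constants=C, **args)
            assert np.allclose(mid, w * hi + (1 - w) * lo)

    def test_noiseless_signal_nonnegative(self):
        assert np.all(two_stage_dm(TI, 0.1, 80, 1.2, 0.3, 0.7, 1.4, 1.0, C) >= 0)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(alpha=1.2),
            dict(lambda_bp=-0.1),
            dict(tau=0.0),
            dict(ti_grid=(0.4, 0.2)),
        ],
    )
    def test_invalid_constants_rejected(self, bad):
        with pytest.raises(ValueError):
            AcquisitionConstants(**bad)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SingleStageParams(BAT=-0.1, CBF=50.0)
        with pytest.raises(ValueError):
            TwoStageParams(BAT=0.1, CBF=50, pcTT=0.9, f_pc=1.2, BAT_c=0.9)


class TestOracleEquivalence:
    def test_single_stage_matches_numerical_convolution(self):
        dm = single_stage_dm(TI, 0.1, 50.0, 1.1, 1.0, C, tau=0.4)
        oracle = numeric_single_stage(TI, 0.1, 50.0, 1.1, 1.0, C, tau=0.4)
        assert relerr(dm, oracle) < 1e-3

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        bat=st.floats(0.0, 1.2),
        cbf=st.floats(5.0, 150.0),
        pctt=st.floats(0.05, 1.5),
        f_pc=st.floats(0.0, 1.0),
        bat_c=st.floats(0.0, 1.5),
        t1t=st.floats(0.7, 1.8),
    )
    def test_two_stage_matches_numerical_convolution(self, bat, cbf, pctt, f_pc, bat_c, t1t):
        dm = two_stage_dm(TI, bat, cbf, pctt, f_pc, bat_c, t1t, 1.0, C)
        oracle = numeric_two_stage(TI, bat, cbf, pctt, f_pc, bat_c, t1t, 1.0, C)
        assert relerr(dm, oracle) < 1e-3

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        bat=st.floats(0.0, 1.2),
        cbf=st.floats(5.0, 150.0),
        pctt=st.floats(0.05, 1.5),
        f_pc=st.floats(0.01, 0.99),
        bat_c=st.floats(0.0, 1.5),
    )
    def test_two_stage_continuous_in_parameters(self, bat, cbf, pctt, f_pc, bat_c):
        """A small step in any parameter moves dM by a proportionally small amount."""
        base = two_stage_dm(TI, bat, cbf, pctt, f_pc, bat_c, 1.1, 1.0, C)
        eps = 1e-6
        scale = max(np.max(base), 1e-9)
        for shifted in (
            two_stage_dm(TI, bat + eps, cbf, pctt, f_pc, bat_c, 1.1, 1.0, C),
            two_stage_dm(TI, bat, cbf + eps, pctt, f_pc, bat_c, 1.1, 1.0, C),
            two_stage_dm(TI, bat, cbf, pctt + eps, f_pc, bat_c, 1.1, 1.0, C),
            two_stage_dm(TI, bat, cbf, pctt, f_pc + eps, bat_c, 1.1, 1.0, C),
            two_stage_dm(TI, bat, cbf, pctt, f_pc, bat_c + eps, 1.1, 1.0, C),
        ):
            assert np.max(np.abs(shifted - base)) < 1e-3 * scale
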