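"""Kinetic models for the pulsed-ASL difference signal dM(t).

Two models of the control-minus-label difference signal measured at a set
of inflow times (TIs) are provided:

* the single-stage general kinetic model for pulsed ASL (plug-flow boxcar
  delivery, single-compartment tissue residue, instantaneous exchange of
  blood water with tissue on arrival), and
* a two-stage model in which the voxel signal is a weighted sum of a
  non-exchanging pre-capillary component (weight ``f_pc``) and an
  exchanging capillary component (weight ``1 - f_pc``).  The two stages
  are kinetically independent: the capillary bolus arrival time ``BAT_c``
  is a free parameter, not ``BAT + pcTT``, because pre-capillary vessels
  in a voxel may feed capillary beds outside it.

Both models are the convolution

    dM(t) = 2 * M0b * f * (c ** (r * m))(t)

of the arterial delivery function ``c`` with the product of a residue
function ``r`` and a longitudinal-relaxation function ``m``, where ``f``
is perfusion in ml/g/s.  All convolutions are evaluated in closed form;
the test-suite cross-checks them against a brute-force trapezoidal
numerical convolution.

Units: times are seconds throughout.  CBF is carried in the conventional
ml/100 g/min and converted by 1/6000 to ml/g/s inside the kinetic
expressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CBF_UNIT_SCALE",
    "AcquisitionConstants",
    "SingleStageParams",
    "TwoStageParams",
    "SignalCurve",
    "delivery_function",
    "single_stage_signal",
    "two_stage_signal",
    "single_stage_dm",
    "two_stage_dm",
    "pre_capillary_dm",
]

#: ml/100 g/min -> ml/g/s
CBF_UNIT_SCALE = 1.0 / 6000.0

DEFAULT_TI_GRID = tuple(np.round(np.arange(0.2, 2.41, 0.2), 10))


def _as_grid(ti) -> np.ndarray:
    t = np.asarray(ti, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("TI grid must be a non-empty 1-D array")
    if np.any(t <= 0) or np.any(np.diff(t) <= 0):
        raise ValueError("TI grid must be strictly increasing and positive")
    return t


@dataclass(frozen=True)
class AcquisitionConstants:
    """Fixed physical and sequence constants of the ASL acquisition.

    Parameters
    ----------
    alpha : float
        Inversion efficiency of the tagging pulse, in [0, 1].
    lambda_bp : float
        Blood/tissue water partition coefficient, ml/g.
    T1b : float
        Longitudinal relaxation time of arterial blood, s.
    tau : float
        Bolus duration of the labelled blood, s.
    ti_grid : tuple of float
        Ordered inflow times at which dM is sampled, s.
    """

    alpha: float = 1.0
    lambda_bp: float = 0.9
    T1b: float = 1.3
    tau: float = 0.7
    ti_grid: tuple = field(default_factory=lambda: DEFAULT_TI_GRID)

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.lambda_bp <= 0 or self.T1b <= 0 or self.tau <= 0:
            raise ValueError("lambda_bp, T1b and tau must be positive")
        grid = tuple(float(t) for t in np.atleast_1d(np.asarray(self.ti_grid, float)))
        _as_grid(grid)
        object.__setattr__(self, "ti_grid", grid)

    def with_tau(self, tau: float) -> "AcquisitionConstants":
        return replace(self, tau=tau)


@dataclass(frozen=True)
class SingleStageParams:
    """Free parameters of the single-stage model plus the tissue T1."""

    BAT: float  # bolus arrival time, s
    CBF: float  # cerebral blood flow, ml/100 g/min
    T1t: float = 1.1  # tissue longitudinal relaxation time, s

    def __post_init__(self):
        if self.BAT < 0 or self.CBF < 0:
            raise ValueError("BAT and CBF must be non-negative")
        if self.T1t <= 0:
            raise ValueError("T1t must be positive")


@dataclass(frozen=True)
class TwoStageParams:
    """Free parameters of the two-stage model plus the tissue T1.

    ``BAT`` is the arrival time of labelled blood in the voxel
    (pre-capillary stage), ``BAT_c`` the arrival time at the capillary
    bed; the two are independent.  ``f_pc`` is the fraction of the total
    ASL signal attributed to the pre-capillary stage and ``pcTT`` the
    pre-capillary transit time.
    """

    BAT: float
    CBF: float
    pcTT: float
    f_pc: float
    BAT_c: float
    T1t: float = 1.1

    def __post_init__(self):
        if min(self.BAT, self.CBF, self.pcTT, self.BAT_c) < 0:
            raise ValueError("BAT, CBF, pcTT and BAT_c must be non-negative")
        if not 0.0 <= self.f_pc <= 1.0:
            raise ValueError("f_pc must lie in [0, 1]")
        if self.T1t <= 0:
            raise ValueError("T1t must be positive")


@dataclass(frozen=True)
class SignalCurve:
    """A dM curve sampled at a set of inflow times."""

    ti: np.ndarray
    dM: np.ndarray

    def __post_init__(self):
        ti = np.asarray(self.ti, dtype=float)
        dM = np.asarray(self.dM, dtype=float)
        if ti.shape != dM.shape or ti.ndim != 1:
            raise ValueError("ti and dM must be 1-D arrays of equal length")
        if not np.all(np.isfinite(dM)):
            raise ValueError("dM must be finite")
        object.__setattr__(self, "ti", ti)
        object.__setattr__(self, "dM", dM)

    def __len__(self):
        return self.ti.size

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"TI": self.ti, "dM": self.dM})


def delivery_function(t, BAT: float, constants: AcquisitionConstants) -> np.ndarray:
    """Normalized arterial magnetization concentration c(t) arriving at a voxel.

    Plug-flow boxcar of duration ``tau`` starting at ``BAT``, decaying
    with the T1 of arterial blood:

        c(t) = alpha * exp(-t / T1b)   for BAT <= t < BAT + tau, else 0.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    if BAT < 0:
        raise ValueError("BAT must be non-negative")
    inside = (t >= BAT) & (t < BAT + constants.tau)
    return np.where(inside, constants.alpha * np.exp(-t / constants.T1b), 0.0)


def _exp_diff(a: np.ndarray, s1, s2) -> np.ndarray:
    """(exp(-a*s1) - exp(-a*s2)) / a with the a -> 0 limit (s2 - s1).

    Evaluated as exp(-a*s1) * (-expm1(-a*(s2-s1))) / a for stability.
    """
    a = np.asarray(a, dtype=float)
    d = np.asarray(s2, dtype=float) - np.asarray(s1, dtype=float)
    small = np.abs(a * d) < 1e-12
    safe_a = np.where(small, 1.0, a)
    out = np.exp(-a * np.asarray(s1, float)) * (-np.expm1(-safe_a * d)) / safe_a
    return np.where(small, np.exp(-a * np.asarray(s1, float)) * d, out)


def single_stage_dm(
    t,
    BAT: float,
    CBF: float,
    T1t: float,
    M0b: float,
    constants: AcquisitionConstants,
    tau: float | None = None,
) -> np.ndarray:
    """Closed-form single-stage dM(t) at arbitrary times ``t``.

    Residue r(u) = exp(-f*u/lambda), relaxation m(u) = exp(-u/T1t) for
    time-since-arrival u; delivery decays with T1b until arrival.  The
    convolution has three regimes (before arrival, during bolus passage,
    after bolus end) and reduces to

        dM(t) = 2*M0b*alpha*f * exp(-k*t) * Phi(BAT, min(t, BAT+tau))

    with f = CBF/6000, k = f/lambda + 1/T1t and
    Phi(s1, s2) = (exp(-a*s1) - exp(-a*s2)) / a for a = 1/T1b - k.
    """
    t = np.asarray(t, dtype=float)
    tau = constants.tau if tau is None else float(tau)
    f = CBF * CBF_UNIT_SCALE
    k = f / constants.lambda_bp + 1.0 / T1t
    a = 1.0 / constants.T1b - k
    upper = np.clip(t, BAT, BAT + tau)
    dm = 2.0 * M0b * constants.alpha * f * np.exp(-k * t) * _exp_diff(a, BAT, upper)
    return np.where(t <= BAT, 0.0, dm)


def pre_capillary_dm(
    t,
    BAT: float,
    CBF: float,
    pcTT: float,
    M0b: float,
    constants: AcquisitionConstants,
    tau: float | None = None,
) -> np.ndarray:
    """Closed-form dM(t) of the non-exchanging pre-capillary stage.

    The residue is a unit boxcar of duration ``pcTT`` after arrival (the
    label transits the vessel without exchanging or clearing by flow) and
    relaxation proceeds with the blood T1 throughout, so the integrand
    collapses to alpha*exp(-t/T1b) over the overlap of the delivery
    window [BAT, BAT+tau) with the residue window (t-pcTT, t]:

        dM(t) = 2*M0b*alpha*f * exp(-t/T1b)
                * max(0, min(t, BAT+tau) - max(BAT, t - pcTT))
    """
    t = np.asarray(t, dtype=float)
    tau = constants.tau if tau is None else float(tau)
    f = CBF * CBF_UNIT_SCALE
    overlap = np.minimum(t, BAT + tau) - np.maximum(BAT, t - pcTT)
    overlap = np.clip(overlap, 0.0, None)
    return 2.0 * M0b * constants.alpha * f * np.exp(-t / constants.T1b) * overlap


def two_stage_dm(
    t,
    BAT: float,
    CBF: float,
    pcTT: float,
    f_pc: float,
    BAT_c: float,
    T1t: float,
    M0b: float,
    constants: AcquisitionConstants,
) -> np.ndarray:
    """Closed-form two-stage dM(t): weighted sum of the two components.

    dM(t) = f_pc * dM_pc(t; BAT, pcTT)  +  (1 - f_pc) * dM_cap(t; BAT_c)

    where the capillary component is the single-stage kinetics with
    delivery arriving at ``BAT_c`` and tissue relaxation ``T1t``, and the
    pre-capillary component keeps the blood T1.  CBF, tau and alpha are
    shared between the stages.
    """
    dm = 0.0
    if f_pc > 0.0:
        dm = f_pc * pre_capillary_dm(t, BAT, CBF, pcTT, M0b, constants)
    if f_pc < 1.0:
        dm = dm + (1.0 - f_pc) * single_stage_dm(t, BAT_c, CBF, T1t, M0b, constants)
    return np.asarray(dm, dtype=float) + np.zeros_like(np.asarray(t, dtype=float))


def single_stage_signal(
    params: SingleStageParams,
    M0b: float,
    constants: AcquisitionConstants,
    tau: float | None = None,
) -> SignalCurve:
    """Single-stage dM sampled on the acquisition TI grid."""
    ti = np.asarray(constants.ti_grid, dtype=float)
    dm = single_stage_dm(ti, params.BAT, params.CBF, params.T1t, M0b, constants, tau=tau)
    return SignalCurve(ti=ti, dM=dm)


def two_stage_signal(
    params: TwoStageParams,
    M0b: float,
    constants: AcquisitionConstants,
) -> SignalCurve:
    """Two-stage dM sampled on the acquisition TI grid."""
    ti = np.asarray(constants.ti_grid, dtype=float)
    dm = two_stage_dm(
        ti,
        params.BAT,
        params.CBF,
        params.pcTT,
        params.f_pc,
        params.BAT_c,
        params.T1t,
        M0b,
        constants,
    )
    return SignalCurve(ti=ti, dM=dm)
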