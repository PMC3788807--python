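"""Synthetic multi-TI ASL data: biphasic curves and a 4-D digital phantom.

The biphasic curve generator emulates a gray-matter voxel containing both
exchanging capillaries and non-exchanging arteries/arterioles.  Two
sources are simulated *independently with the single-stage model* — a
fast-arriving, short-bolus pre-capillary source and a later capillary
source — and mixed as

    dM_tot(TI) = f_pc * dM_1(TI) + (1 - f_pc) * dM_2(TI).

Note that both sources deliberately use the tissue T1 in their relaxation
term, while the two-stage *fitting* model relaxes the pre-capillary stage
with the blood T1: this generator/model mismatch is part of the study
design being emulated and is what pushes the two-stage fitted CBF above
the generating value.

The phantom builder lays out pure-tissue, pure-artery, mixed and
background-noise regions on a small 3-D grid and produces the matching
4-D dM volume, 4-D inversion-recovery volume, masks and ground truth for
end-to-end pipeline tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import (
    AcquisitionConstants,
    SignalCurve,
    SingleStageParams,
    single_stage_signal,
)

__all__ = [
    "SimulationSpec",
    "PhantomSpec",
    "Phantom",
    "generate_fpc_series",
    "add_noise",
    "generate_phantom",
    "ir_forward",
    "DEFAULT_IR_TIS",
]

#: inversion-recovery sampling times used for T1t/M0t calibration, s
DEFAULT_IR_TIS = (0.2, 0.6, 1.4, 2.4)


def ir_forward(ti, T1t: float, M0t: float) -> np.ndarray:
    """Magnitude inversion-recovery signal M0t * |1 - 2 exp(-TI/T1t)|."""
    ti = np.asarray(ti, dtype=float)
    if T1t <= 0:
        raise ValueError("T1t must be positive")
    return M0t * np.abs(1.0 - 2.0 * np.exp(-ti / T1t))


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the biphasic-curve simulation.

    Defaults are the gray-matter voxel conditions: stage 1 (pre-capillary
    source) BAT=0.1 s, tau=0.4 s, CBF=50 ml/100 g/min; stage 2 (capillary
    source) BAT=0.9 s, tau=0.7 s, CBF=50; T1t=1.1 s, T1b=1.3 s; sampled
    at TIs 0.2-2.4 s in 0.2 s steps.
    """

    stage1: SingleStageParams = field(
        default_factory=lambda: SingleStageParams(BAT=0.1, CBF=50.0, T1t=1.1)
    )
    stage2: SingleStageParams = field(
        default_factory=lambda: SingleStageParams(BAT=0.9, CBF=50.0, T1t=1.1)
    )
    tau1: float = 0.4
    tau2: float = 0.7
    f_pc_values: tuple = field(default_factory=lambda: tuple(np.round(np.arange(0.0, 1.01, 0.1), 10)))
    constants: AcquisitionConstants = field(default_factory=AcquisitionConstants)
    M0b: float = 1.0
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if any(not 0.0 <= f <= 1.0 for f in self.f_pc_values):
            raise ValueError("f_pc values must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("bolus durations must be positive")


def generate_fpc_series(spec: SimulationSpec) -> dict[float, SignalCurve]:
    """Noiseless (or noisy, if ``noise_sd > 0``) biphasic curves per f_pc.

    Returns a dict mapping each f_pc value to its mixed curve.
    """
    c1 = single_stage_signal(spec.stage1, spec.M0b, spec.constants, tau=spec.tau1)
    c2 = single_stage_signal(spec.stage2, spec.M0b, spec.constants, tau=spec.tau2)
    rng = np.random.default_rng(spec.seed)
    out: dict[float, SignalCurve] = {}
    for f_pc in spec.f_pc_values:
        dm = f_pc * c1.dM + (1.0 - f_pc) * c2.dM
        if spec.noise_sd > 0:
            dm = dm + rng.normal(0.0, spec.noise_sd, size=dm.shape)
        out[float(f_pc)] = SignalCurve(ti=c1.ti, dM=dm)
    return out


def add_noise(curve: SignalCurve, noise_sd: float, seed=None) -> SignalCurve:
    """Add iid zero-mean Gaussian noise to a curve; reproducible under seed."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd == 0:
        return curve
    rng = np.random.default_rng(seed)
    return SignalCurve(ti=curve.ti, dM=curve.dM + rng.normal(0.0, noise_sd, size=curve.dM.shape))


# ---------------------------------------------------------------------------
# digital phantom


@dataclass(frozen=True)
class PhantomSpec:
    """Layout and ground truth of the digital perfusion phantom.

    The default 16x16x4 grid contains a pure-tissue block, a pure-artery
    block (fast-arriving short bolus), a mixed block generated from the
    two-source sum at ``mixed_f_pc``, and background voxels holding noise
    only.  ``noise_sd`` applies to every dM sample; IR volumes receive
    ``ir_noise_sd``.  Signal units are scaled so that M0t is ``M0t`` in
    tissue-bearing voxels.
    """

    shape: tuple = (16, 16, 4)
    constants: AcquisitionConstants = field(default_factory=AcquisitionConstants)
    ir_tis: tuple = DEFAULT_IR_TIS
    tissue: SingleStageParams = field(
        default_factory=lambda: SingleStageParams(BAT=0.7, CBF=60.0, T1t=1.1)
    )
    artery: SingleStageParams = field(
        default_factory=lambda: SingleStageParams(BAT=0.2, CBF=80.0, T1t=1.1)
    )
    mixed_f_pc: float = 0.5
    mixed_stage1: SingleStageParams = field(
        default_factory=lambda: SingleStageParams(BAT=0.1, CBF=50.0, T1t=1.1)
    )
    mixed_stage2: SingleStageParams = field(
        default_factory=lambda: SingleStageParams(BAT=0.9, CBF=50.0, T1t=1.1)
    )
    mixed_tau1: float = 0.4
    M0t: float = 1000.0
    # peak dM in the weakest (mixed) region is ~2.7 signal units at
    # M0t = 1000, so the default noise gives a peak-SNR of ~10 there
    noise_sd: float = 0.25
    ir_noise_sd: float = 5.0
    seed: int = 0

    def region_labels(self) -> np.ndarray:
        """Integer region map: 0 background, 1 tissue, 2 artery, 3 mixed."""
        nx, ny, nz = self.shape
        lab = np.zeros(self.shape, dtype=np.int8)
        if nx < 12 or ny < 12 or nz < 1:
            raise ValueError("phantom grid must be at least 12x12x1")
        lab[2:6, 2:6, :] = 1
        lab[2:4, 8:12, :] = 2
        lab[8:12, 8:12, :] = 3
        return lab


@dataclass(frozen=True)
class Phantom:
    """A generated phantom: volumes, masks and the generating truth."""

    dm: np.ndarray  # (x, y, z, n_ti)
    ir: np.ndarray  # (x, y, z, n_ir_ti)
    brain_mask: np.ndarray  # bool, tissue-bearing voxels
    region_labels: np.ndarray  # int8 region map
    spec: PhantomSpec

    @property
    def background_mask(self) -> np.ndarray:
        return self.region_labels == 0

    def region_mask(self, label: int) -> np.ndarray:
        return self.region_labels == label


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Build the 4-D dM and IR volumes voxel by region, bit-reproducibly."""
    rng = np.random.default_rng(spec.seed)
    C = spec.constants
    ti = np.asarray(C.ti_grid)
    ir_ti = np.asarray(spec.ir_tis, dtype=float)
    labels = spec.region_labels()
    M0b = spec.M0t / C.lambda_bp

    curves = {
        1: single_stage_signal(spec.tissue, M0b, C).dM,
        2: single_stage_signal(spec.artery, M0b, C).dM,
    }
    s1 = single_stage_signal(spec.mixed_stage1, M0b, C, tau=spec.mixed_tau1).dM
    s2 = single_stage_signal(spec.mixed_stage2, M0b, C).dM
    curves[3] = spec.mixed_f_pc * s1 + (1.0 - spec.mixed_f_pc) * s2

    dm = np.zeros(spec.shape + (ti.size,))
    ir = np.zeros(spec.shape + (ir_ti.size,))
    for lab, curve in curves.items():
        dm[labels == lab] = curve
    t1t = {1: spec.tissue.T1t, 2: spec.artery.T1t, 3: spec.mixed_stage2.T1t}
    for lab in (1, 2, 3):
        ir[labels == lab] = ir_forward(ir_ti, t1t[lab], spec.M0t)

    if spec.noise_sd > 0:
        dm = dm + rng.normal(0.0, spec.noise_sd, size=dm.shape)
    if spec.ir_noise_sd > 0:
        ir = ir + rng.normal(0.0, spec.ir_noise_sd, size=ir.shape)

    return Phantom(
        dm=dm,
        ir=ir,
        brain_mask=labels > 0,
        region_labels=labels,
        spec=spec,
    )


def ground_truth_params(spec: PhantomSpec) -> dict[int, dict]:
    """Generating parameters per region label (1 tissue, 2 artery, 3 mixed).

    The mixed region is generated from two single-stage sources, so only
    the quantities the two-source construction pins down are listed for
    it (the shared CBF, the mixing fraction, and the source arrival
    times); a two-stage fit's pcTT has no exact generating counterpart.
    """
    return {
        1: {"BAT": spec.tissue.BAT, "CBF": spec.tissue.CBF, "T1t": spec.tissue.T1t},
        2: {"BAT": spec.artery.BAT, "CBF": spec.artery.CBF, "T1t": spec.artery.T1t},
        3: {
            "CBF": spec.mixed_stage2.CBF,
            "f_pc": spec.mixed_f_pc,
            "BAT": spec.mixed_stage1.BAT,
            "BAT_c": spec.mixed_stage2.BAT,
            "T1t": spec.mixed_stage2.T1t,
        },
    }
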