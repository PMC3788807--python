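"""Volume-level processing: subtraction, calibration, noise filtering,
voxelwise dual-model fitting and parameter-map I/O.

The entry point is :func:`fit_volume`, which takes an :class:`ASLStudy`
(4-D dM volume, 4-D inversion-recovery volume, brain mask) and produces
:class:`ParameterMaps`: per-voxel CBF, BAT, f_pc, pcTT, BAT_c, pcCBV and
the BIC of each model with the per-voxel model choice.  Voxels failing
the noise filter are left undefined (NaN).

All volumes are NIfTI-1; the TI lists and acquisition constants travel
in a YAML sidecar config, not in the image headers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .fitting import (
    InversionRecoveryModel,
    SingleStageModel,
    TwoStageModel,
    compute_M0b,
    select_model,
)
from .kinetics import AcquisitionConstants
from .simulation import DEFAULT_IR_TIS

log = logging.getLogger("aslkin")

__all__ = [
    "ASLStudy",
    "ParameterMaps",
    "compute_difference",
    "noise_filter",
    "fit_volume",
    "compute_pcCBV",
    "load_config",
    "save_config",
]

MAP_NAMES = (
    "CBF",
    "BAT",
    "f_pc",
    "pcTT",
    "BAT_c",
    "pcCBV",
    "CBF_single",
    "BAT_single",
    "BIC_single",
    "BIC_two",
    "T1t",
    "M0t",
)


def compute_difference(control: np.ndarray, label: np.ndarray) -> np.ndarray:
    """Control-minus-label difference signal dM, per TI.

    Arrays are (x, y, z, TI) or (x, y, z, TI, repeat); repeats are
    averaged after subtraction (equivalent either way for a linear
    operation).
    """
    control = np.asarray(control, dtype=float)
    label = np.asarray(label, dtype=float)
    if control.shape != label.shape:
        raise ValueError("control and label volumes must have matching shapes")
    dm = control - label
    if dm.ndim == 5:
        dm = dm.mean(axis=-1)
    return dm


def noise_filter(
    dm: np.ndarray,
    brain_mask: np.ndarray,
    noise_mask: np.ndarray | None = None,
    factor: float = 3.0,
    statistic: str = "voxel_peak",
) -> np.ndarray:
    """Inclusion mask: brain voxels whose peak dM clears the noise level.

    A voxel is kept iff ``max over TIs of dM >= factor * noise_level``.
    The noise region defaults to the complement of the brain mask.

    ``statistic`` selects how the scalar noise level is computed:

    * ``"voxel_peak"`` (default) — mean over noise voxels of each
      voxel's peak |dM|, i.e. the same quantity the filter thresholds.
    * ``"sample_abs"`` — mean of |dM| over all noise voxels and TIs.

    Difference-image noise is approximately zero-mean, so a signed mean
    would be degenerate; both statistics are magnitude levels.  The
    default compares like with like (peak against mean peak), which for
    Gaussian noise rejects essentially all pure-noise voxels at the
    conventional factor of 3; the per-sample mean sits ~2.5x lower and
    lets roughly a tenth of noise voxels through.
    """
    dm = np.asarray(dm, dtype=float)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if dm.ndim != 4 or brain_mask.shape != dm.shape[:3]:
        raise ValueError("dm must be 4-D and brain_mask must match its spatial shape")
    if noise_mask is None:
        noise_mask = ~brain_mask
    noise_mask = np.asarray(noise_mask, dtype=bool)
    if not noise_mask.any():
        raise ValueError("noise region is empty")
    if statistic == "voxel_peak":
        noise_level = float(np.abs(dm[noise_mask]).max(axis=-1).mean())
    elif statistic == "sample_abs":
        noise_level = float(np.abs(dm[noise_mask]).mean())
    else:
        raise ValueError(f"unknown noise statistic {statistic!r}")
    peak = dm.max(axis=-1)
    return brain_mask & (peak >= factor * noise_level)


def compute_pcCBV(cbf_map: np.ndarray, pctt_map: np.ndarray) -> np.ndarray:
    """Pre-capillary CBV via the central volume theorem, voxelwise.

    pcCBV = CBF * pcTT / 60 (ml/100 g), computed per voxel *before* any
    ROI averaging — a mean of products is not a product of means.
    """
    cbf_map = np.asarray(cbf_map, dtype=float)
    pctt_map = np.asarray(pctt_map, dtype=float)
    if cbf_map.shape != pctt_map.shape:
        raise ValueError("CBF and pcTT maps must be aligned")
    return cbf_map * pctt_map / 60.0


@dataclass
class ASLStudy:
    """One multi-TI ASL acquisition ready for voxelwise fitting."""

    dm: np.ndarray  # (x, y, z, n_ti)
    ti: tuple  # ASL inflow times, s
    ir: np.ndarray  # (x, y, z, n_ir_ti)
    brain_mask: np.ndarray  # 3-D, nonzero = brain
    ir_tis: tuple = DEFAULT_IR_TIS
    noise_mask: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.dm = np.asarray(self.dm, dtype=float)
        self.ir = np.asarray(self.ir, dtype=float)
        self.brain_mask = np.asarray(self.brain_mask) != 0
        if self.dm.ndim != 4 or self.ir.ndim != 4:
            raise ValueError("dm and ir must be 4-D (x, y, z, TI)")
        if self.dm.shape[:3] != self.ir.shape[:3] or self.dm.shape[:3] != self.brain_mask.shape:
            raise ValueError("spatial dimensions of dm, ir and brain_mask must agree")
        if self.dm.shape[3] != len(self.ti):
            raise ValueError("4th dm dimension must match the TI list")
        if self.ir.shape[3] != len(self.ir_tis):
            raise ValueError("4th ir dimension must match the IR TI list")
        if self.noise_mask is not None:
            self.noise_mask = np.asarray(self.noise_mask) != 0

    @classmethod
    def from_files(cls, dm_path, ir_path, brain_mask_path, config: dict,
                   noise_mask_path=None) -> "ASLStudy":
        dm_img = nib.load(str(dm_path))
        ir_img = nib.load(str(ir_path))
        mask_img = nib.load(str(brain_mask_path))
        noise = None
        if noise_mask_path is not None:
            noise = np.asanyarray(nib.load(str(noise_mask_path)).dataobj)
        return cls(
            dm=np.asanyarray(dm_img.dataobj),
            ti=tuple(config["ti_asl"]),
            ir=np.asanyarray(ir_img.dataobj),
            ir_tis=tuple(config.get("ti_ir", DEFAULT_IR_TIS)),
            brain_mask=np.asanyarray(mask_img.dataobj),
            noise_mask=noise,
            affine=dm_img.affine,
        )


@dataclass
class ParameterMaps:
    """Voxelwise fitted-parameter maps plus model choice and masks.

    ``model_choice`` codes: 0 undefined, 1 single-stage preferred,
    2 two-stage preferred.  All float maps are NaN outside the inclusion
    mask.  Two-stage parameters are carried in every included voxel;
    mask them post hoc with ``model_choice`` if only the preferred
    model's values are wanted.
    """

    maps: dict
    model_choice: np.ndarray
    inclusion_mask: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __getitem__(self, name: str) -> np.ndarray:
        if name == "model_choice":
            return self.model_choice
        return self.maps[name]

    @property
    def two_stage_fraction(self) -> float:
        """% of included voxels preferring the two-stage model."""
        n = int(self.inclusion_mask.sum())
        if n == 0:
            return np.nan
        return 100.0 * float((self.model_choice == 2).sum()) / n

    def to_dir(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, arr in self.maps.items():
            img = nib.Nifti1Image(arr.astype(np.float64), self.affine)
            nib.save(img, outdir / f"{name}.nii.gz")
        nib.save(
            nib.Nifti1Image(self.model_choice.astype(np.int16), self.affine),
            outdir / "model_choice.nii.gz",
        )
        nib.save(
            nib.Nifti1Image(self.inclusion_mask.astype(np.uint8), self.affine),
            outdir / "inclusion_mask.nii.gz",
        )

    @classmethod
    def from_dir(cls, outdir) -> "ParameterMaps":
        outdir = Path(outdir)
        maps = {}
        for name in MAP_NAMES:
            p = outdir / f"{name}.nii.gz"
            if p.exists():
                img = nib.load(str(p))
                maps[name] = np.asanyarray(img.dataobj).astype(np.float64)
        choice_img = nib.load(str(outdir / "model_choice.nii.gz"))
        incl = np.asanyarray(nib.load(str(outdir / "inclusion_mask.nii.gz")).dataobj) != 0
        return cls(
            maps=maps,
            model_choice=np.asanyarray(choice_img.dataobj).astype(np.int16),
            inclusion_mask=incl,
            affine=choice_img.affine,
        )


def fit_volume(
    study: ASLStudy,
    constants: AcquisitionConstants | None = None,
    noise_factor: float = 3.0,
    noise_statistic: str = "voxel_peak",
    progress_every: int = 50,
) -> ParameterMaps:
    """Voxelwise calibration, dual-model fitting and BIC model selection.

    Per included voxel: fit T1t/M0t from the inversion-recovery series,
    derive M0b = M0t/lambda, fit the single- and two-stage kinetic
    models to the dM series, compute both BICs (N = number of TIs,
    k = 2 and 5) and record the preferred model.  Per-voxel failures are
    logged and masked, not fatal.
    """
    C = constants if constants is not None else AcquisitionConstants(ti_grid=tuple(study.ti))
    if tuple(np.round(C.ti_grid, 9)) != tuple(np.round(study.ti, 9)):
        C = AcquisitionConstants(
            alpha=C.alpha, lambda_bp=C.lambda_bp, T1b=C.T1b, tau=C.tau, ti_grid=tuple(study.ti)
        )
    inclusion = noise_filter(
        study.dm, study.brain_mask, study.noise_mask, factor=noise_factor,
        statistic=noise_statistic,
    )
    shape = study.brain_mask.shape
    maps = {name: np.full(shape, np.nan) for name in MAP_NAMES}
    choice = np.zeros(shape, dtype=np.int16)

    voxels = np.argwhere(inclusion)
    if voxels.size == 0:
        log.warning("inclusion mask is empty: no voxels passed the noise filter")
        return ParameterMaps(maps=maps, model_choice=choice,
                             inclusion_mask=inclusion, affine=study.affine)
    log.info("fitting %d voxels", len(voxels))
    fitted = np.zeros(shape, dtype=bool)
    for i, (x, y, z) in enumerate(voxels):
        try:
            ir_fit = InversionRecoveryModel(study.ir[x, y, z], ti=study.ir_tis).fit()
            if not np.isfinite(ir_fit.T1t) or ir_fit.M0t <= 0:
                log.warning("voxel (%d,%d,%d): IR calibration failed, masking", x, y, z)
                continue
            m0b = compute_M0b(ir_fit.M0t, C.lambda_bp)
            dm = study.dm[x, y, z]
            res_s = SingleStageModel(dm, ti=study.ti, m0b=m0b, t1t=ir_fit.T1t, constants=C).fit()
            res_t = TwoStageModel(dm, ti=study.ti, m0b=m0b, t1t=ir_fit.T1t, constants=C).fit()
        except Exception:  # pragma: no cover - defensive per-voxel guard
            log.exception("voxel (%d,%d,%d): fit failed, masking", x, y, z)
            continue
        maps["T1t"][x, y, z] = ir_fit.T1t
        maps["M0t"][x, y, z] = ir_fit.M0t
        maps["CBF_single"][x, y, z] = res_s.params["CBF"]
        maps["BAT_single"][x, y, z] = res_s.params["BAT"]
        maps["BIC_single"][x, y, z] = res_s.bic
        maps["BIC_two"][x, y, z] = res_t.bic
        for name in ("CBF", "BAT", "pcTT", "f_pc", "BAT_c"):
            maps[name][x, y, z] = res_t.params[name]
        choice[x, y, z] = 2 if select_model(res_s, res_t) == "two" else 1
        fitted[x, y, z] = True
        if progress_every and (i + 1) % progress_every == 0:
            log.info("fitted %d / %d voxels", i + 1, len(voxels))
    maps["pcCBV"] = compute_pcCBV(maps["CBF"], maps["pcTT"])
    return ParameterMaps(maps=maps, model_choice=choice,
                         inclusion_mask=inclusion & fitted, affine=study.affine)


# ---------------------------------------------------------------------------
# sidecar config


def default_config(constants: AcquisitionConstants | None = None) -> dict:
    C = constants if constants is not None else AcquisitionConstants()
    return {
        "ti_asl": [float(t) for t in C.ti_grid],
        "ti_ir": [float(t) for t in DEFAULT_IR_TIS],
        "alpha": C.alpha,
        "lambda": C.lambda_bp,
        "tau": C.tau,
        "T1b": C.T1b,
        "noise_filter_factor": 3.0,
    }


def constants_from_config(config: dict) -> AcquisitionConstants:
    return AcquisitionConstants(
        alpha=float(config.get("alpha", 1.0)),
        lambda_bp=float(config.get("lambda", 0.9)),
        T1b=float(config.get("T1b", 1.3)),
        tau=float(config.get("tau", 0.7)),
        ti_grid=tuple(config["ti_asl"]),
    )


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
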