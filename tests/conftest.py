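import numpy as np
import pytest

from aslkin.kinetics import AcquisitionConstants
from aslkin.pipeline import ASLStudy, fit_volume
from aslkin.simulation import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def constants() -> AcquisitionConstants:
    return AcquisitionConstants()


@pytest.fixture(scope="session")
def tiny_phantom_spec() -> PhantomSpec:
    """Single-slice phantom, small enough for repeated voxelwise fits."""
    return PhantomSpec(shape=(12, 12, 1), seed=11)


@pytest.fixture(scope="session")
def fitted_tiny_phantom(tiny_phantom_spec):
    """The tiny noisy phantom run through the full voxelwise pipeline once."""
    phantom = generate_phantom(tiny_phantom_spec)
    study = ASLStudy(
        dm=phantom.dm,
        ti=tiny_phantom_spec.constants.ti_grid,
        ir=phantom.ir,
        brain_mask=phantom.brain_mask,
        ir_tis=tiny_phantom_spec.ir_tis,
    )
    maps = fit_volume(study, progress_every=0)
    return phantom, maps
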