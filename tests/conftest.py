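import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from nanobiopsy.sicm_model import PipetteGeometry
from nanobiopsy.trace_sim import (
    CellPreset,
    InjectionProtocol,
    NoiseModel,
    calibrate_extraction_example,
    default_aqueous_electrics,
)

PRINTED_EXTRACTION = {"pre_hold_nA": 0.35, "peak_nA": 2.83, "post_hold_nA": 0.70}


@pytest.fixture(scope="session")
def aqueous_electrics():
    return default_aqueous_electrics()


@pytest.fixture(scope="session")
def short_injection_protocol():
    # trace length kept manageable by shortening the post-injection hold
    return InjectionProtocol(hold_duration=2.0)


@pytest.fixture(scope="session")
def default_noise():
    return NoiseModel()


@pytest.fixture(scope="session")
def quiet_noise():
    return NoiseModel(white_sd=0.0)


@pytest.fixture(scope="session")
def glial_cell():
    return CellPreset()


@pytest.fixture(scope="session")
def printed_extraction_setup():
    """Protocol + pipette calibrated to the printed extraction trace."""
    return calibrate_extraction_example(PRINTED_EXTRACTION)


@pytest.fixture(scope="session")
def aqueous_geometry():
    return PipetteGeometry(r_tip=75e-9, taper=0.0714, length=5e-3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
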