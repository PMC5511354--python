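import numpy as np
import pytest

from gshquant.binding import (
    FLUORIMETER_PHOTOPHYSICS,
    HELA_FACS_PHOTOPHYSICS,
    BindingParameters,
)
from gshquant.calibration import HELA_CALIBRATION


@pytest.fixture
def bp():
    """Binding parameters at the probe's measured dissociation constant."""
    return BindingParameters(kd=3.7e-3)


@pytest.fixture
def ph_fluorimeter():
    return FLUORIMETER_PHOTOPHYSICS


@pytest.fixture
def ph_facs():
    return HELA_FACS_PHOTOPHYSICS


@pytest.fixture
def hela_cal():
    return HELA_CALIBRATION


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
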