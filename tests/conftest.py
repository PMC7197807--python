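import numpy as np
import pytest

from iokinetics.model_core import (
    AVERAGE_PATIENT,
    PATIENT_PARAMETER_ROWS,
    patient_parameters,
)
from iokinetics.observation import ScanSchedule

SCAN_TIMES = np.array([1.0, 4.0, 24.0, 48.0, 72.0, 168.0])


@pytest.fixture
def q0():
    return np.array([1.0, 0.0, 0.0, 0.0, 0.0])


@pytest.fixture
def scan_times():
    return SCAN_TIMES.copy()


@pytest.fixture
def schedule():
    return ScanSchedule()


@pytest.fixture
def patient1_params():
    return patient_parameters(*PATIENT_PARAMETER_ROWS[0])


@pytest.fixture
def average_params():
    return AVERAGE_PATIENT
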