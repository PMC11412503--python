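import math

import numpy as np
import pytest

from myot2 import AcquisitionParams, MuscleMask, PhantomSpec, make_phantom

TE_30 = 9.0 * np.arange(1, 31)


@pytest.fixture(scope="session")
def acq_small() -> AcquisitionParams:
    """Desk-scale acquisition: full echo train, reduced matrix."""
    return AcquisitionParams(matrix_size=(64, 64), n_slices=2, fov_mm=(35.0, 35.0))


@pytest.fixture(scope="session")
def acq_tiny() -> AcquisitionParams:
    return AcquisitionParams(matrix_size=(48, 48), n_slices=1, fov_mm=(35.0, 35.0))


@pytest.fixture(scope="session")
def noiseless_healthy(acq_small):
    """Severity-0 noise-free phantom and its true mask."""
    spec = PhantomSpec(seed=11, severity=0.0, snr=math.inf)
    stack, truth = make_phantom(spec, acq_small)
    return stack, truth, MuscleMask(labels=truth.mask_true)


@pytest.fixture(scope="session")
def noiseless_severe(acq_small):
    """Severity-1 noise-free phantom: all three tissue T2 classes present."""
    spec = PhantomSpec(seed=11, severity=1.0, snr=math.inf)
    stack, truth = make_phantom(spec, acq_small)
    return stack, truth, MuscleMask(labels=truth.mask_true)
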