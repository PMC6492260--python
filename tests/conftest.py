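import numpy as np
import pytest

from asldesign import (
    AcquisitionConstants,
    PhysioParams,
    builtin_protocol,
    calibrated_noise,
    make_att_prior,
)


@pytest.fixture(scope="session")
def acq():
    return AcquisitionConstants()


@pytest.fixture(scope="session")
def phys_mid():
    return PhysioParams(cbf=50.0, att=1.0)


@pytest.fixture(scope="session")
def default_prior():
    """The standard grey-matter ATT prior (coarsened for test speed)."""
    return make_att_prior(0.5, 1.8, 0.3, step=0.005)


@pytest.fixture(scope="session")
def noise(acq):
    return calibrated_noise(acq)


@pytest.fixture(scope="session")
def reference_protocol():
    return builtin_protocol("reference_multi_pld")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
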