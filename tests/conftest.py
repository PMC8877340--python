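import numpy as np
import pytest

from anmbrsim import (CakeParams, DepositionParams, FlocculationParams,
                      OpsPoint)


@pytest.fixture
def floc_params():
    return FlocculationParams()


@pytest.fixture
def cake_params():
    return CakeParams()


@pytest.fixture
def dep_params():
    return DepositionParams()


@pytest.fixture
def reactor_ops():
    """Typical AnMBR membrane operating point (SI units)."""
    return OpsPoint(J=1.94e-6, J20=1.82e-6, uG=0.003, HMT=1.0, G=171.6,
                    dp=4.5e-5, mu=7.2e-4)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
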