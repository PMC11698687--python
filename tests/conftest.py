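import numpy as np
import pytest

from pdbsi.core_io import make_scheme
from pdbsi.model import build_dictionary


@pytest.fixture(scope="session")
def exvivo_scheme():
    """86 weightings to b=4500 s/mm² + 8 b0, Δ=16 ms, δ=7 ms."""
    return make_scheme(86, 4500.0, 8, 16.0, 7.0, seed=1)


@pytest.fixture(scope="session")
def invivo_scheme():
    """86 weightings to b=900 s/mm² + 8 b0."""
    return make_scheme(86, 900.0, 8, 32.0, 16.0, seed=1)


@pytest.fixture(scope="session")
def dictionary():
    return build_dictionary()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def _two_pool_signal(scheme, restricted_fraction, d_restricted=0.3, d_free=2.0):
    b = scheme.bvals * 1.0e-3
    return restricted_fraction * np.exp(-b * d_restricted) + (
        1.0 - restricted_fraction
    ) * np.exp(-b * d_free)


@pytest.fixture(scope="session")
def two_pool_signal():
    """Factory: noiseless mixture of two isotropic pools (normalized)."""
    return _two_pool_signal
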