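import numpy as np
import pytest

from qlin import ChR2Kinetics, QuasiLinearParams, preset


@pytest.fixture(scope="session")
def row70():
    """Resonant somatic parameter set (fitted at -70 mV)."""
    return preset("soma_-70mV")


@pytest.fixture(scope="session")
def row55():
    """Amplifying-only somatic parameter set (fitted at -55 mV)."""
    return preset("soma_-55mV")


@pytest.fixture(scope="session")
def passive_params():
    return QuasiLinearParams.passive(tau_m=26.1, amp_scale=1.0)


@pytest.fixture(scope="session")
def kin():
    """ChR2 kinetics used across optogenetic tests."""
    return ChR2Kinetics(tau_r=2.0, tau_d=18.0, gain=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
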