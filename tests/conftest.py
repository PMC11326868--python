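import numpy as np
import pytest

from mocsyn.model import ChannelSet, PassiveProps, build_model
from mocsyn.morphology import Morphology, Section, moc_fixture


@pytest.fixture(scope="session")
def soma_only():
    """Single-compartment morphology for fast integrator tests."""
    return Morphology([Section("soma", 33.6, 6.1, nseg=1, swc_type=1)])


@pytest.fixture(scope="session")
def passive_channels():
    return ChannelSet(
        densities={"leak": {"all": 2.0e-4}},
        e_leak=-60.0,
    )


@pytest.fixture(scope="session")
def passive_soma_model(soma_only, passive_channels):
    m = build_model(soma_only, PassiveProps(), passive_channels)
    m.calibrated = True
    m.set_holding(-60.0, settle_ms=200.0)
    return m


@pytest.fixture(scope="session")
def fixture_morph():
    return moc_fixture()


@pytest.fixture(scope="session")
def calibrated_model():
    """The shipped calibrated MOC model, holding established (slow; shared)."""
    from mocsyn.experiments import default_model

    return default_model()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
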