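import numpy as np
import pytest

from rppgflow import (
    FlowOpticsParams,
    PressureOpticsParams,
    ProtocolSpec,
    VesselModel,
    load_constants,
)


@pytest.fixture(scope="session")
def constants():
    return load_constants()


@pytest.fixture
def vessel():
    return VesselModel()


@pytest.fixture
def stiff_vessel():
    return VesselModel(is_stiff=True)


@pytest.fixture
def pressure_params():
    return PressureOpticsParams()


@pytest.fixture
def flow_params():
    return FlowOpticsParams()


def noiseless(**kwargs) -> ProtocolSpec:
    """ProtocolSpec with all channel noise switched off."""
    base = dict(noise_pressure=0.0, noise_flow=0.0, noise_ppg=0.0, noise_diameter=0.0)
    base.update(kwargs)
    return ProtocolSpec(**base)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
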