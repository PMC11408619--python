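import numpy as np
import pytest

from riboforce import synthetic_data as sd


@pytest.fixture(scope="session")
def control_model():
    return sd.KineticModel()


@pytest.fixture(scope="session")
def ramp_protocol():
    return sd.ProtocolParams(n_cycles=50)


@pytest.fixture(scope="session")
def control_ramp_trace(control_model, ramp_protocol):
    """One 50-cycle control ramp trace with its ground-truth events."""
    return sd.simulate_ramp_trace(control_model, ramp_protocol, 0.0, rng=101)


@pytest.fixture(scope="session")
def control_cf_trace(control_model):
    """One 30-min constant-force control trace with ground truth."""
    proto = sd.ProtocolParams(kind="constant_force", hold_force=7.0, hold_duration=1800.0)
    return sd.simulate_constant_force_trace(control_model, proto, 0.0, rng=202)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
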