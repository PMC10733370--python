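import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=list(HealthCheck)
)
settings.load_profile("ci")

import okrcircuit as oc
from okrcircuit.circuit_model import synthetic_bank


@pytest.fixture(scope="session")
def drum():
    """Default oscillatory drum: +/-5 deg, 0.4 Hz, 10 s, no padding."""
    return oc.DrumStimulus()


@pytest.fixture(scope="session")
def bank():
    """Noise-free template bank built through the full calcium pipeline."""
    return synthetic_bank(seed=0)
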