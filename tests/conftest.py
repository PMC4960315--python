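import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nichetrack.io_formats import AnalysisParameters

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def params():
    """Default analysis parameters with a set detection threshold."""
    return AnalysisParameters(intensity_threshold=50.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
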