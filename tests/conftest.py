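import pytest
from hypothesis import HealthCheck, settings

from seagrass_mutualism import ModelParameters

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    """Default (field-calibrated) parameter set."""
    return ModelParameters()
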