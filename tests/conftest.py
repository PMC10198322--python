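import pytest
from hypothesis import HealthCheck, settings

from quadscan import ProjectionModel

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def model15():
    return ProjectionModel(15.0)


@pytest.fixture(scope="session")
def model30():
    return ProjectionModel(30.0)
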