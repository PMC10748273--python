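import pytest
from hypothesis import HealthCheck, settings

from fracrisk.synthetic import generate_study, study_fixture

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_sites():
    """The 16-site survey-like dataset under the fixture's default seed."""
    return generate_study(study_fixture())
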