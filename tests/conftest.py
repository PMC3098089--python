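import pytest
from hypothesis import HealthCheck, settings

from gotaxon.fixtures import paper_fixture

settings.register_profile(
    "repro",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def fx():
    """The hand-built worked-example fixture (read-only across tests)."""
    return paper_fixture()
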