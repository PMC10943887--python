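import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def coloring_net():
    from treefeat import fixtures

    return fixtures.coloring_model(fixtures.reference_coloring_instance())
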