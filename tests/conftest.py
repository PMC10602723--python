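import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_data():
    from indexweaver import reference_fixture

    return reference_fixture()


@pytest.fixture()
def weighted_fixture(fixture_data):
    """Fixture hierarchy with combination weights computed (fresh copy)."""
    from indexweaver import IndexHierarchy, combination_weights

    h = IndexHierarchy.from_dict(fixture_data.hierarchy.to_dict())
    return combination_weights(h)
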