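import pytest
from hypothesis import HealthCheck, settings

from camnav import ThermoConstants, load_reference_affinities

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def constants():
    return ThermoConstants()


@pytest.fixture(scope="session")
def affinity_tables():
    return load_reference_affinities()


@pytest.fixture(scope="session")
def nav14_long(affinity_tables):
    return affinity_tables[("NaV1.4", "Long")]


@pytest.fixture(scope="session")
def nav15_long(affinity_tables):
    return affinity_tables[("NaV1.5", "Long")]
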