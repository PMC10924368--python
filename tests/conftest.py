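import pytest
from hypothesis import HealthCheck, settings

from bpsdmon.regularities import load_table
from bpsdmon.simulation import Room

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def psyco_table():
    return load_table("psyco")


@pytest.fixture(scope="session")
def bephyen_table():
    return load_table("bephyen")


@pytest.fixture(scope="session")
def rooms():
    return {name: Room.load(name) for name in ("room1", "room2", "room3")}
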