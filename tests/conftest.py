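import pytest
from hypothesis import HealthCheck, settings

from taguchigrow import generate_l27, load_fixture

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def dm():
    return generate_l27(6)


@pytest.fixture(scope="session")
def lettuce():
    return load_fixture("lettuce", "all")


@pytest.fixture(scope="session")
def basil():
    return load_fixture("basil", "all")


# The study's printed 27-run coded trial matrix, transcribed independently
# of the generator: one 6-digit string per run (CO2, LED, EC, day temp,
# night temp, humidity).
PRINTED_L27 = [
    "111111", "111122", "111133", "122211", "122222", "122233",
    "133311", "133322", "133333", "212312", "212323", "212331",
    "223112", "223123", "223131", "231212", "231223", "231231",
    "313213", "313221", "313232", "321313", "321321", "321332",
    "332113", "332121", "332132",
]


@pytest.fixture(scope="session")
def printed_matrix():
    return [[int(c) for c in row] for row in PRINTED_L27]
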