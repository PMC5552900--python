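import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from onenest.splits import CircularOrdering, SplitSystem, make_split


@pytest.fixture
def ground5():
    return frozenset("12345")


@pytest.fixture
def crossing_pair(ground5):
    """The incompatible pair whose closure is the worked example."""
    return (
        make_split({"1", "2"}, ground5),
        make_split({"2", "3"}, ground5),
    )


@pytest.fixture
def worked_system(crossing_pair, ground5):
    return SplitSystem.from_splits(set(crossing_pair), ground5)


def ordering(n: int) -> CircularOrdering:
    return CircularOrdering.from_sequence([str(i) for i in range(1, n + 1)])


@pytest.fixture
def ordering5():
    return ordering(5)
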