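import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from eventscan import EventCounts, RegionData, line_region

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_region() -> RegionData:
    """Four cells on a line with populations 10, 20, 30, 40."""
    return RegionData(
        ("a", "b", "c", "d"),
        np.array([10, 20, 30, 40]),
        line_region([10, 20, 30, 40]).neighbour_order,
    )


@pytest.fixture
def toy_events() -> EventCounts:
    """Histogram with Y=2: per-cell (c_i1, c_i2) = events (3, 2, 4, 1)."""
    hist = np.array([[1, 1], [2, 0], [0, 2], [1, 0]])
    return EventCounts(case_histogram=hist)
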