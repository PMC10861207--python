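import numpy as np
import pytest

from nemaspan import EventTable


@pytest.fixture
def uniform_deaths() -> EventTable:
    """Four deaths at t = 1..4, no censoring: the textbook KM staircase."""
    return EventTable(["a", "b", "c", "d"], ["g"] * 4, [1, 2, 3, 4], [1] * 4)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
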