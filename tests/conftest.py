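import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

import grmcal as g


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid():
    return g.make_grid(61, -4.0, 4.0)


@pytest.fixture
def small_pool(rng):
    """80 operational items, mixed boundary counts."""
    return g.generate_item_pool(80, (2, 3, 4, 5), rng, id_prefix="op")


@pytest.fixture
def unit_item():
    """Unit-slope 3-category item on the D=1 metric (hand-checkable)."""
    return g.GRMItem("u", 1.0, (-1.0, 1.0), D=1.0)


def random_item(rng, f=None, D=1.7):
    f = f or int(rng.integers(1, 6))
    a = float(np.exp(rng.normal(0, 0.5)))
    b = np.sort(rng.normal(0, 1, f))
    while np.any(np.diff(b) <= 0):
        b = np.sort(rng.normal(0, 1, f))
    return g.GRMItem("r", a, tuple(b), D)
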