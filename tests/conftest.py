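import numpy as np
import pytest

from climwindows import make_world
from climwindows.hexgrid import build_hex_grid


@pytest.fixture(scope="session")
def world():
    """Default synthetic world, shared across the suite (seed 1)."""
    return make_world(seed=1)


@pytest.fixture(scope="session")
def small_grid():
    """A small all-land hex grid (~a few hundred nodes) for fast graph tests."""
    return build_hex_grid((30.0, 50.0, 5.0, 18.0), 55.0, elevation=lambda lo, la: np.full(lo.size, 100.0))
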