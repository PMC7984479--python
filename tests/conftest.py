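import numpy as np
import pytest

from betapet.geometry import ActivityVolume, GridGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_grid():
    """Single-slice 24x24 grid at the default in-plane pitch."""
    return GridGeometry((1, 24, 24), (2.8, 2.73, 2.73))


@pytest.fixture
def toy_volume(small_grid):
    """Hot square on a warm square background."""
    values = np.zeros(small_grid.shape)
    values[0, 4:20, 4:20] = 1.0
    values[0, 9:15, 9:15] = 4.0
    return ActivityVolume(small_grid, values)
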