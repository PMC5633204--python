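import numpy as np
import pytest

from angionorm.grid_core import Grid, ScalarField


@pytest.fixture
def small_grid() -> Grid:
    return Grid(8, 8, 0.1)


@pytest.fixture
def medium_grid() -> Grid:
    return Grid(21, 21, 0.1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_field(grid: Grid, rng: np.random.Generator, positive: bool = False) -> ScalarField:
    values = rng.standard_normal(grid.shape)
    if positive:
        values = np.abs(values)
    return ScalarField(grid, values)
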