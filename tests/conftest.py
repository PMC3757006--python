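import numpy as np
import pytest

from cardioraman import default_grid, default_library


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture
def cubic_background(grid):
    """Fluorescence-like positive decreasing cubic, height 5 at 520 cm⁻¹."""
    t = (grid - grid[0]) / (grid[-1] - grid[0])
    return 5.0 * (1.0 - 0.9 * t + 0.15 * t**2 + 0.05 * t**3)
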