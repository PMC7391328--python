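import numpy as np
import pytest

from quadpat import PointPattern, Window, make_subblock_grid, simulate_csr


@pytest.fixture
def unit_window():
    return Window(0.0, 0.0, 1.0, 1.0)


@pytest.fixture
def plot_window():
    return Window(0.0, 0.0, 5.0, 5.0)


@pytest.fixture
def plot_grid():
    return make_subblock_grid(5.0, 5.0, 0.5)


@pytest.fixture
def csr100(unit_window):
    return simulate_csr(unit_window, 100, np.random.default_rng(42))


@pytest.fixture
def small_pattern(unit_window):
    """A fixed 12-point pattern for exact oracle comparisons."""
    rng = np.random.default_rng(7)
    return PointPattern(rng.uniform(0.05, 0.95, size=(12, 2)), unit_window)
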