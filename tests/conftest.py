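import numpy as np
import pytest

from seaplan.grid import PlanningGrid, ScoredLayer


@pytest.fixture
def grid10():
    """Small 10x10 grid with 10-ac cells."""
    return PlanningGrid(n_rows=10, n_cols=10, origin=(0.0, 10 * 201.1680))


@pytest.fixture
def grid20():
    return PlanningGrid(n_rows=20, n_cols=20)


def make_layer(grid, values, name="test"):
    vals = np.asarray(values, dtype=float)
    vals = np.where(grid.study_mask, vals, np.nan)
    return ScoredLayer(grid, vals, name=name)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
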