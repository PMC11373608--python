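import numpy as np
import pytest

from asgnn.graph import SpotGrid, build_grid_graph
from asgnn.simulate import SyntheticSpec, simulate_dataset


def full_grid(rows, cols):
    coords = [(r, c) for r in range(rows) for c in range(cols)]
    ids = tuple(f"s{r}x{c}" for r, c in coords)
    return SpotGrid(ids, np.array(coords))


@pytest.fixture
def grid_3x3():
    return full_grid(3, 3)


@pytest.fixture
def graph_3x3(grid_3x3):
    return build_grid_graph(grid_3x3)


@pytest.fixture(scope="session")
def toy_dataset():
    """Small planted-domain study shared by the slower integration tests."""
    spec = SyntheticSpec(rows=12, cols=12, occupancy=0.9, n_domains=3,
                         d_x=8, d_y=12, n_sections=4, seed=11)
    return spec, simulate_dataset(spec)
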