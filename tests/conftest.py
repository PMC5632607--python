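import numpy as np
import pytest

from admkit.grids import EnvStack, GridGeometry
from admkit.occurrences import OccurrenceSet
from admkit.synthetic import gen_env_stack, gen_virtual_species, sample_occurrences


@pytest.fixture(scope="session")
def geometry30() -> GridGeometry:
    return GridGeometry(30, 30, 0.0, 30_000.0, 1000.0)


@pytest.fixture(scope="session")
def stack30() -> EnvStack:
    """Small correlated landscape shared by oracle tests."""
    return gen_env_stack(seed=42, n_layers=4, n_rows=30, n_cols=30, autocorr_range=3.0)


@pytest.fixture(scope="session")
def stack60() -> EnvStack:
    return gen_env_stack(seed=7, n_layers=6, n_rows=60, n_cols=60, autocorr_range=5.0)


@pytest.fixture(scope="session")
def planted60(stack60):
    """Virtual species with a planted niche plus a museum-style sample."""
    vs = gen_virtual_species(stack60, seed=11, marginality_target=1.0, tolerance_target=0.5)
    occ = sample_occurrences(vs, n=200, seed=13)
    return vs, occ


def cell_center_points(geometry: GridGeometry, cells: np.ndarray) -> np.ndarray:
    """Map (row, col) pairs to cell-center coordinates."""
    s = geometry.cell_size
    x = geometry.origin_x + (cells[:, 1] + 0.5) * s
    y = geometry.origin_y - (cells[:, 0] + 0.5) * s
    return np.column_stack([x, y])


@pytest.fixture(scope="session")
def occ_from_cells():
    def make(geometry, cells, species="sp", source="field"):
        return OccurrenceSet(species, cell_center_points(geometry, np.asarray(cells)), source)

    return make
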