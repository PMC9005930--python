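import numpy as np
import pandas as pd
import pytest

import seedmenus as sm
from seedmenus.model_space import ModelSpec


@pytest.fixture(scope="session")
def small_stack():
    """48x48, 4-covariate autocorrelated landscape used across tests."""
    return sm.make_landscape(48, 48, 1.0, 4, 3.0, seed=3)


@pytest.fixture(scope="session")
def signal_species(small_stack):
    """Range-restricted virtual species responding strongly to SP and Tmax.

    The low intercept makes ~4% of cells suitable, emulating the narrow
    niches of priority restoration taxa; broad-ranged species are much
    harder to discriminate from random background by construction.
    """
    return sm.make_virtual_species(small_stack, ["SP", "Tmax"], [3.0, -3.0],
                                   intercept=-8.0, species_id="sig")


@pytest.fixture(scope="session")
def presence_cells(small_stack, signal_species):
    occ = sm.sample_occurrences(signal_species, 300, seed=5)
    clean, _ = sm.qc_filter(occ, small_stack)
    return sm.rasterize_presences(clean, small_stack.grid)


@pytest.fixture(scope="session")
def species_data(small_stack, presence_cells):
    return sm.SpeciesData("sig", small_stack, presence_cells)


@pytest.fixture()
def toy_grid():
    return sm.GridSpec(nrows=10, ncols=10, cell_km=1.0)


def toy_stack(values: dict[str, np.ndarray], cell_km: float = 1.0):
    """Build a tiny stack from explicit layer arrays."""
    first = next(iter(values.values()))
    grid = sm.GridSpec(nrows=first.shape[0], ncols=first.shape[1],
                       cell_km=cell_km)
    return sm.CovariateStack(grid, {k: np.asarray(v, dtype=float)
                                    for k, v in values.items()})
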