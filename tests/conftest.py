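import numpy as np
import pytest

from heatmargin.phylo import read_newick
from heatmargin.simulate import (GridSpec, SimConfig, simulate_operative_temps,
                                 simulate_traits, simulate_trait_table,
                                 simulate_tree)


@pytest.fixture(scope="session")
def three_tip_tree():
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def tree50():
    return simulate_tree(50, seed=7)


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec(lat_min=-3, lat_max=3, lon_min=0, lon_max=2)


@pytest.fixture(scope="session")
def small_config(small_grid):
    return SimConfig(n_species=40, prop_missing=0.5, seed=11, grid=small_grid,
                     max_band_cells=3)


@pytest.fixture(scope="session")
def small_truth_table(small_config):
    tree = simulate_tree(small_config.n_species, seed=small_config.seed)
    rng = np.random.default_rng(small_config.seed)
    truth = simulate_traits(tree, small_config, rng=rng)
    table = simulate_trait_table(truth, small_config, rng=rng)
    return tree, truth, table


@pytest.fixture(scope="session")
def temps_one_cell():
    grid = GridSpec(lat_min=0, lat_max=1, lon_min=0, lon_max=1)
    return simulate_operative_temps(grid, range(2005, 2016), "terrestrial",
                                    0.0, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
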