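import numpy as np
import pytest

from genoscape.synthio import (SimConfig, simulate_climate_stack, simulate_dem,
                               simulate_genotypes, simulate_world)


@pytest.fixture(scope="session")
def cfg():
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def world(cfg):
    return simulate_world(cfg)


@pytest.fixture(scope="session")
def genotypes(world):
    return world.genotypes


@pytest.fixture(scope="session")
def climate(world):
    return world.climate_current


@pytest.fixture(scope="session")
def dem(world):
    return world.dem


@pytest.fixture(scope="session")
def small_genotypes():
    """A small, fast genotype table (8 pops x 20 diploids x 6 loci)."""
    cfg = SimConfig(n_pops=8, n_ind_per_pop=20, n_loci=6, n_clusters=3,
                    deme_size=60, n_generations=30, seed=5)
    return simulate_genotypes(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
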