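import numpy as np
import pytest

import metaclock as mc


@pytest.fixture(scope="session")
def population():
    """Default 20-genotype panel with simulated death tables (fixed seed)."""
    specs, tables = mc.simulate_population(seed=3)
    return specs, tables


@pytest.fixture(scope="session")
def demo(population):
    specs, tables = population
    return mc.summarize_demography(tables)


@pytest.fixture(scope="session")
def lifespans(population):
    specs, _ = population
    return {s.genotype_id: s.mean_lifespan() for s in specs}


@pytest.fixture(scope="session")
def metabolome_sim(population, lifespans):
    """Raw matrix + truth labels under the default planted-effect config."""
    specs, _ = population
    raw, truth = mc.simulate_metabolome(
        specs, mc.MetabolomeSimConfig(seed=7), lifespans=lifespans
    )
    return raw, truth


@pytest.fixture(scope="session")
def norm_mat(metabolome_sim):
    from metaclock.metabolome import preprocess

    raw, _ = metabolome_sim
    return preprocess(raw)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
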