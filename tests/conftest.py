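import numpy as np
import pytest

import phytoclines as pc


@pytest.fixture(scope="session")
def small_config():
    """Default study dimensions with a small trait panel."""
    return pc.SimulationConfig(traits=pc.simulate.default_traits(6), seed=11)


@pytest.fixture(scope="session")
def small_tree(small_config):
    return pc.simulate_tree(
        small_config.n_species, 52.0, seed=11, labels=small_config.species_ids
    )


@pytest.fixture(scope="session")
def small_study(small_config, small_tree):
    tt = pc.simulate_traits(small_config, small_tree)
    return {
        "config": small_config,
        "tree": small_tree,
        "traits": tt,
        "sites": small_config.sites(),
        "species": small_config.species(),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
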