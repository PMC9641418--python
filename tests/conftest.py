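import numpy as np
import pytest

import glycomsi as g
from glycomsi import mass_ladder as ml


@pytest.fixture(scope="session")
def default_ladder():
    return ml.build_ladder(3, 25, phospho_max=1, adducts=(ml.Adduct.sodium,),
                           mz_window=(500.0, 3000.0))


@pytest.fixture(scope="session")
def small_sim():
    """A small seeded two-region section shared across tests."""
    cfg = g.default_two_region_config(seed=11, width=16, height=12)
    dataset, truth = g.simulate(cfg)
    return cfg, dataset, truth


@pytest.fixture(scope="session")
def full_sim():
    """The default 40x40 two-region section (the study conditions)."""
    cfg = g.default_two_region_config(seed=7)
    dataset, truth = g.simulate(cfg)
    return cfg, dataset, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
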