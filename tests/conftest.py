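import numpy as np
import pytest

from hierdsm import simulator as sim


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_survey():
    """A small ship-only synthetic survey shared across tests."""
    design = sim.SimDesign(base_seed=7, n_cells=400, n_surveyed=150)
    rng = np.random.default_rng(7)
    truth = sim.simulate_landscape(design, rng)
    cells, sightings = sim.simulate_survey(truth, design, rng)
    return design, truth, cells, sightings


@pytest.fixture(scope="session")
def mixed_platform_survey():
    """A synthetic survey with both ship and aerial platforms."""
    design = sim.SimDesign(base_seed=11, n_cells=500, n_surveyed=240,
                           aerial_fraction=0.5, availability=0.37,
                           aerial_sigma_km=0.15, aerial_trunc_W_km=0.3)
    rng = np.random.default_rng(11)
    truth = sim.simulate_landscape(design, rng)
    cells, sightings = sim.simulate_survey(truth, design, rng)
    return design, truth, cells, sightings
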