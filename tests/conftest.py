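import numpy as np
import pytest

import paleorange as pr


@pytest.fixture(scope="session")
def small_grid() -> pr.GridSpec:
    return pr.GridSpec(n_rows=40, n_cols=40, x_min=0.0, y_min=20.0, cell_size=0.5)


@pytest.fixture(scope="session")
def small_world(small_grid):
    """A 40x40 synthetic world with K=4 past scenarios, shared across tests."""
    config = pr.WorldConfig(
        grid=small_grid, n_scenarios=4, scenario_noise_sd=0.5, seed=11
    )
    present, past = pr.generate_climate(config)
    return config, present, past


@pytest.fixture(scope="session")
def cold_species_setup(small_world):
    """A realized mid-gradient species with polygons and a sampled table."""
    config, present, past = small_world
    truth = pr.NicheTruth("testsp", ("bio01",), (10.0,), (2.0,), 0.15)
    occ = pr.realize_species(truth, present)
    polys = pr.polygons_from_occupancy(occ, config.grid, 2, species="testsp")
    table = pr.sample_occurrences(present, polys, 80, 80, seed=3)
    return truth, occ, polys, table
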