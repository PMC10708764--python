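import numpy as np
import pandas as pd
import pytest

from forestagb import SimulationConfig, generate_inventory, generate_raster_stack


@pytest.fixture(scope="session")
def default_inventory():
    """One full-size inventory (354 plots) shared across tests."""
    cfg = SimulationConfig(seed=11)
    return cfg, generate_inventory(cfg)


@pytest.fixture(scope="session")
def small_raster():
    """A small clean inventory + raster stack for feature/mapping tests."""
    cfg = SimulationConfig(n_plots=40, outlier_fraction=0.0, seed=5)
    inv = generate_inventory(cfg)
    stack, pixels = generate_raster_stack(cfg, grid_shape=(32, 32), inventory=inv)
    return cfg, inv, stack, pixels


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
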