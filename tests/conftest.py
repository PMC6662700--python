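"""Shared fixtures: one small simulated fleet reused across the suite."""

import numpy as np
import pandas as pd
import pytest

from eetolab.config import FleetConfig, RunConfig
from eetolab.world import default_world
from eetolab import synthetic, tracks, grounds


@pytest.fixture(scope="session")
def world():
    return default_world()


@pytest.fixture(scope="session")
def small_config():
    return FleetConfig(n_vessels=15, undisturbed_days=120, disturbed_days=40, seed=7)


@pytest.fixture(scope="session")
def fleet(small_config, world):
    return synthetic.generate_fleet(small_config, world)


@pytest.fixture(scope="session")
def sim(small_config, world, fleet):
    """Undisturbed-period simulation: (pings, trips, labels)."""
    return synthetic.simulate_tracks(fleet, world, small_config)


@pytest.fixture(scope="session")
def disturbed(small_config, world, fleet, sim):
    """Closure-period simulation: (pings, trips, labels, exit_flags)."""
    return synthetic.simulate_disturbance(fleet, world, small_config, sim)


@pytest.fixture(scope="session")
def cleaned(sim, world):
    pings, _, _ = sim
    return tracks.clean_pings(pings, world.extent, depth_fn=world.depth_fn)


@pytest.fixture(scope="session")
def features(cleaned, world):
    return tracks.derive_features(cleaned, port=world.port)


@pytest.fixture(scope="session")
def truth_classified(cleaned):
    """Cleaned pings carrying the generator's true activity as the label."""
    out = cleaned.copy()
    out["activity"] = out["activity_true"]
    return out


@pytest.fixture(scope="session")
def grid(truth_classified):
    fishing = truth_classified.loc[truth_classified["activity"] == "fishing"]
    return grounds.build_grid(fishing, n=30)


@pytest.fixture(scope="session")
def visitation(truth_classified, grid, small_config):
    return grounds.build_visitation_series(truth_classified, grid, small_config.ping_interval)
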