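import numpy as np
import pandas as pd
import pytest

from thermoce import io
from thermoce.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def fixture_dataset():
    """Small synthetic monitoring bundle: 6 sites x 50 species x 15 years."""
    cfg = SimulationConfig(n_sites=6, n_species=50, survey_years=(1993, 2007), seed=42)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def fixture_paths(fixture_dataset, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    io.write_csv(fixture_dataset.observations, out / "observations.csv")
    io.write_csv(fixture_dataset.sites, out / "sites.csv")
    io.write_csv(fixture_dataset.sti, out / "sti.csv")
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def random_series(rng, n_species=5, n_surveys=6, irregular=False):
    """Random small occupancy series for oracle cross-checks."""
    from thermoce import OccupancySeries

    if irregular:
        gaps = rng.integers(1, 4, size=n_surveys - 1)
        times = np.concatenate([[2000.0], 2000.0 + np.cumsum(gaps)])
    else:
        times = 2000.0 + np.arange(n_surveys, dtype=float)
    states = rng.integers(0, 2, size=(n_species, n_surveys))
    return OccupancySeries("rnd", times, states)


def markov_series(rng, c=0.3, e=0.4, n_species=30, n_surveys=20):
    """Regular annual series simulated from the two-state model itself."""
    from thermoce import OccupancySeries, transition_matrix

    P = transition_matrix(c, e, 1.0)
    states = np.empty((n_species, n_surveys), dtype=int)
    states[:, 0] = rng.random(n_species) < c / (c + e)
    for t in range(1, n_surveys):
        p = np.where(states[:, t - 1] == 1, P[1, 1], P[0, 1])
        states[:, t] = rng.random(n_species) < p
    return OccupancySeries("mkv", 2000.0 + np.arange(n_surveys, dtype=float), states)
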