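import warnings

import numpy as np
import pandas as pd
import pytest

from pairspace.io import RunConfig
from pairspace.simulate import (
    SimulationConfig,
    datasets_to_tables,
    simulate_pair_dataset,
)

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def run_config():
    return RunConfig(seed=0)


@pytest.fixture(scope="session")
def sim_study():
    """Default-condition simulated study (15 follows), seed 0."""
    datasets, truth = simulate_pair_dataset(SimulationConfig(seed=0))
    return datasets, truth


@pytest.fixture(scope="session")
def sim_small():
    """A small 5-follow simulation for I/O and CLI tests."""
    cfg = SimulationConfig(seed=3, n_tags=5, bins_min=4, bins_max=10)
    datasets, truth = simulate_pair_dataset(cfg)
    return datasets, truth


@pytest.fixture(scope="session")
def data_dir(tmp_path_factory, sim_small):
    """The small simulation written out in the on-disk CSV schema."""
    datasets, truth = sim_small
    out = tmp_path_factory.mktemp("simdata")
    for name, df in datasets_to_tables(datasets, truth).items():
        df.to_csv(out / f"{name}.csv", index=False)
    return out


def random_depth_profile(rng, n=400, dt=1.0):
    """A rough random-walk depth trace crossing the 10 m threshold often."""
    steps = rng.normal(0.0, rng.uniform(0.3, 1.5), n)
    depth = np.abs(np.cumsum(steps))
    depth *= rng.uniform(5.0, 25.0) / max(depth.max(), 1e-9)
    t = np.arange(n) * dt
    return t, depth
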