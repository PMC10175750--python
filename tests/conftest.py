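import numpy as np
import pandas as pd
import pytest

from devbias.data import LandmarkConfiguration, ShapeDataset
from devbias.simulate import DEFAULT_MEAN_SHAPE, default_spec


def make_dataset(configs, sides=None, individuals=None, replicates=None):
    """Wrap an (n, k, 2) array as a ShapeDataset."""
    n = len(configs)
    sides = sides or ["none"] * n
    individuals = individuals or [f"s{i}" for i in range(n)]
    replicates = replicates or [1] * n
    obs = [LandmarkConfiguration(ind, side, rep, c)
           for ind, side, rep, c in zip(individuals, sides, replicates, configs)]
    return ShapeDataset(obs, pd.DataFrame({
        "individual": individuals, "side": sides, "measurement": replicates}))


@pytest.fixture(scope="session")
def wing_mean():
    return DEFAULT_MEAN_SHAPE.copy()


@pytest.fixture(scope="session")
def study_spec():
    """Study-condition synthetic spec (87 individuals etc.)."""
    return default_spec(seed=1234)


@pytest.fixture(scope="session")
def small_spec():
    """Reduced design sizes for fast unit tests."""
    return default_spec(
        seed=99,
        n_individuals=30,
        lines_per_population=(4, 4, 4),
        population_latitudes=(40.0, 50.0, 60.0),
        temperatures=(18.0, 28.0),
        n_per_cell=1,
        n_species=12,
        n_per_species=3,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
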