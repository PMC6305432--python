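import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pandagut.matrix import AbundanceMatrix
from pandagut.simulate import SimulationParams, simulate_abundance, simulate_catalog

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_params():
    """A scaled-down study design: fast, but with all planted structure."""
    return SimulationParams(
        n_species=10,
        genes_per_species=(5, 8),
        n_core=8,
        n_keystone=2,
        background_fraction=0.2,
    )


@pytest.fixture(scope="session")
def small_dataset(small_params):
    catalog, truth = simulate_catalog(small_params, seed=7)
    matrix, meta = simulate_abundance(catalog, truth, small_params, seed=8)
    return catalog, truth, matrix, meta


@pytest.fixture()
def random_matrix():
    rng = np.random.default_rng(42)
    df = pd.DataFrame(
        rng.random((100, 33)),
        index=[f"g{i:03d}" for i in range(100)],
        columns=[f"s{i:02d}" for i in range(33)],
    )
    return AbundanceMatrix(df, units="counts")
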