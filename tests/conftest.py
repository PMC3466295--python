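import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from drynet.simulate import SimulationConfig, simulate_dataset

settings.register_profile("default", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study: same design, fewer genes, for fast tests."""
    return SimulationConfig(n_genes=300, genes_per_phenotype=6, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def balanced_design():
    """8 genotypes x 2 treatments x 3 blocks, one sample per cell."""
    rows = [
        (b, f"G{g:02d}", t)
        for b in range(1, 4)
        for g in range(1, 9)
        for t in ("control", "stressed")
    ]
    df = pd.DataFrame(rows, columns=["block", "genotype", "treatment"])
    df.index = pd.Index([f"s{i:02d}" for i in range(len(df))], name="sample")
    return df


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
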