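import numpy as np
import pytest

from capcnv.dataset import build_default_dataset
from capcnv.simulate import SimulationConfig, simulate_reference_pair

DATASET_SEED = 1


@pytest.fixture(scope="session")
def default_ds():
    """The full default synthetic study dataset (tracks + population)."""
    return build_default_dataset(seed=DATASET_SEED)


@pytest.fixture(scope="session")
def refpair():
    """A small reference pair for cheap structural tests."""
    cfg = SimulationConfig(
        n_genes_per_subgenome=5, intergenic_length=3000, seed=7
    )
    return cfg, simulate_reference_pair(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
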