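import numpy as np
import pandas as pd
import pytest

from derepress import SimulationConfig, simulate_dataset

#: small but fully featured simulated experiment shared across test modules
SMALL_CONFIG = SimulationConfig(
    n_genes=1500,
    n_families=10,
    targets_per_family=60,
    reads_per_mirna_scale=30.0,
    rng_seed=101,
)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(SMALL_CONFIG)


@pytest.fixture()
def toy_fc():
    """Fold-change table with 4 targets at log2fc=1 and background {-1, 0, 1}."""
    fc = pd.DataFrame(
        {
            "log2fc": [1.0, 1.0, 1.0, 1.0, -1.0, 0.0, 1.0],
            "mean_expr": [100.0] * 7,
            "expressed": [True] * 7,
        },
        index=pd.Index([f"t{i}" for i in range(4)] + [f"b{i}" for i in range(3)],
                       name="gene_id"),
    )
    return fc


def make_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
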