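import numpy as np
import pytest

from subbias.synthetic_data import (
    PopulationSpec,
    SimulationConfig,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def null_allotriploid_dataset():
    """20 allotriploid samples, 300 ortholog pairs, no allocation bias.

    Full ortholog retention so every gene is a 2n/1n pair; allocation at
    the 1/3 equal-per-copy null.
    """
    cfg = SimulationConfig(
        populations=(
            PopulationSpec("Allo", "allotriploid", 20),
            PopulationSpec("Dip", "diploid", 2),
        ),
        n_genes=300,
        ortholog_retention={"Allo": 1.0},
        library_size=2e5,
        seed=7,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def demo_dataset():
    """Reduced-scale six-population dataset with known bias and DE genes."""
    cfg = SimulationConfig(
        seed=1, n_genes=300, n_bias_genes=12, n_de_genes=18, library_size=2e5
    )
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
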