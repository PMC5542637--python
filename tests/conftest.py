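import numpy as np
import pytest

from lamsite import simulate
from lamsite.model import DEFAULT_ENZYMES


@pytest.fixture(scope="session")
def vector():
    return simulate.default_vector()


@pytest.fixture(scope="session")
def linker():
    return simulate.DEFAULT_LINKER


@pytest.fixture(scope="session")
def enzymes():
    return DEFAULT_ENZYMES


@pytest.fixture(scope="session")
def small_genome():
    """100 kb, 2-chromosome toy genome with 20 genes (seeded)."""
    genome, genes = simulate.make_toy_genome(
        2, [60_000, 40_000], gc_content=0.45, n_genes=8, gene_length=2_000, seed=11
    )
    return genome, genes


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
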