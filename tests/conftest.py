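import numpy as np
import pytest

from umistates.data import CountMatrix, DirichletPrior


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_matrix(rng, n_genes=6, n_cells=12, mean_total=30):
    """Small dense random count matrix with every cell non-empty."""
    base = rng.dirichlet(np.ones(n_genes))
    totals = rng.poisson(mean_total, n_cells) + 1
    counts = np.column_stack([rng.multinomial(t, base) for t in totals])
    return CountMatrix(counts, drop_zero_genes=False)


@pytest.fixture
def small_matrix(rng):
    return random_matrix(rng)


@pytest.fixture
def unit_prior():
    """theta_g = (1, 1): counts over 2 genes integrate Beta(1,1)."""
    return DirichletPrior.uniform(2, 2.0)
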