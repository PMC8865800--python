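import numpy as np
import pandas as pd
import pytest

from primus import CountMatrix, NuisanceDesign, simulate_primus


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts(rng):
    vals = rng.poisson(2.0, size=(30, 40))
    return CountMatrix(vals.astype(np.int64))


@pytest.fixture
def small_dataset():
    """A well-separated draw from the generative model (3 clusters, 2 samples)."""
    return simulate_primus(n_genes=60, n_cells=150, r=2, k=3, seed=11, separation=1.2)


@pytest.fixture
def empty_design():
    def make(n_cells, size_factors=None):
        return NuisanceDesign.empty(n_cells, size_factors)

    return make


@pytest.fixture
def qc_meta():
    return pd.DataFrame(
        {
            "cell_class": ["cancer", "immune", "stromal", "cancer"],
            "reads": [9000, 3000, 5000, 8000],
            "umis": [5000, 1100, 2100, 5000],
            "genes": [1600, 600, 1100, 1600],
            "mito_pct": [10.0, 13.0, 5.0, 10.0],
        },
        index=["c1", "c2", "c3", "c4"],
    )
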