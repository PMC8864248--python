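import numpy as np
import pytest

from scsge import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_matrix(values, normalized=True, genes=None, cells=None):
    """Small ExpressionMatrix with auto-generated identifiers."""
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    genes = genes or [f"g{i}" for i in range(m)]
    cells = cells or [f"c{k}" for k in range(n)]
    return ExpressionMatrix(values, genes, cells, normalized=normalized)


@pytest.fixture
def random_matrix(rng):
    """5 genes x 12 cells, log-normalized, with some exact zeros."""
    vals = rng.lognormal(1.0, 0.5, size=(5, 12))
    vals[rng.random((5, 12)) < 0.25] = 0.0
    return make_matrix(np.log1p(vals))


@pytest.fixture
def continuous_matrix(rng):
    """Tie-free matrix: value-permutation properties need distinct values."""
    return make_matrix(np.log1p(rng.lognormal(1.0, 0.5, size=(5, 12))))
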