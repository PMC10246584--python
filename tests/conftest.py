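import numpy as np
import pytest

from scgpcl import preprocess, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts(rng):
    """A 6x5 integer count fixture with no empty rows/columns."""
    counts = rng.integers(0, 6, size=(6, 5))
    counts[0, 0] = 1  # ensure no zero row/col after the draw
    counts[:, counts.sum(axis=0) == 0] += 1
    counts[counts.sum(axis=1) == 0, 0] += 1
    return counts


@pytest.fixture
def tiny_graph(small_counts):
    cm = preprocess.CountMatrix(
        counts=small_counts,
        cell_ids=[f"c{i}" for i in range(small_counts.shape[0])],
        gene_ids=[f"g{j}" for j in range(small_counts.shape[1])],
    )
    return preprocess.preprocess(cm, F=4, seed=0)[1]


@pytest.fixture
def two_group_counts():
    """Strongly separated two-group fixture (no dropout, big DE factors)."""
    cfg = simulate.SimConfig(
        n_cells=80, n_genes=60, group_probs=(0.5, 0.5),
        de_fac_scale=1.2, dropout_mid=None, seed=7)
    return simulate.simulate_counts(cfg)
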