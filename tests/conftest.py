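import numpy as np
import pytest

from cbea import CompositionTable, SetCollection


@pytest.fixture
def toy_table():
    """4 samples x 5 taxa, strictly positive and closed."""
    rng = np.random.default_rng(17)
    vals = rng.dirichlet(np.ones(5), size=4)
    return CompositionTable(vals, tuple(f"s{i}" for i in range(4)),
                            tuple(f"t{j}" for j in range(5)))


@pytest.fixture
def toy_sets(toy_table):
    """Two sets over the toy taxa: {t0,t1} and its complement {t2,t3,t4}."""
    memb = np.array([[1, 0], [1, 0], [0, 1], [0, 1], [0, 1]])
    return SetCollection(memb, ("front", "back"), toy_table.taxon_ids)


@pytest.fixture
def count_table():
    """Small integer count table containing zeros."""
    rng = np.random.default_rng(5)
    counts = rng.poisson(20, size=(6, 8)).astype(float)
    counts[0, 0] = 0.0
    return CompositionTable(counts, tuple(f"s{i}" for i in range(6)),
                            tuple(f"t{j}" for j in range(8)))
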