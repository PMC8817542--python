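import numpy as np
import pytest

from microclust import DistanceMatrix, OTUTable, parse_newick


@pytest.fixture
def three_leaf_tree():
    """The worked 3-leaf fixture: ((A:1,B:1):1,C:2);"""
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def three_leaf_table():
    """S1 = A+C, S2 = B+C in equal parts (counts 5 each)."""
    return OTUTable(np.array([[5, 0], [0, 5], [5, 5]]), ["A", "B", "C"], ["S1", "S2"])


@pytest.fixture
def two_block_dm():
    """Two well-separated blocks of 5 samples: within 0.1, between 0.9."""
    n = 10
    vals = np.full((n, n), 0.9)
    vals[:5, :5] = 0.1
    vals[5:, 5:] = 0.1
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(vals, [f"S{i}" for i in range(n)])


def make_random_table(rng, p=12, n=8, depth=500):
    """Random dense count table with no all-zero sample."""
    base = rng.dirichlet(np.ones(p))
    counts = np.stack(
        [rng.multinomial(depth, rng.dirichlet(base * 50 + 0.1)) for _ in range(n)],
        axis=1,
    )
    counts[0] += 1  # guarantee every sample has at least one read
    return OTUTable(counts, [f"OTU_{i + 1}" for i in range(p)], [f"S{j + 1}" for j in range(n)])
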