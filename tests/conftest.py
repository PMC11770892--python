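import numpy as np
import pytest

from brainnetkit.graphs import BinaryGraph


def graph_from_edges(n, edges):
    adj = np.zeros((n, n), dtype=int)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    return BinaryGraph(adj)


@pytest.fixture
def path4():
    """Path graph a-b-c-d."""
    return graph_from_edges(4, [(0, 1), (1, 2), (2, 3)])


@pytest.fixture
def star4():
    """Star with center 0 and three leaves."""
    return graph_from_edges(4, [(0, 1), (0, 2), (0, 3)])


@pytest.fixture
def triangle():
    return graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def complete4():
    return graph_from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])
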