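import numpy as np
import pytest

from ridgeconn.connectome import WeightedGraph


def unit_graph(n_nodes, edges):
    """Unit-weight graph from an edge list."""
    ei = np.array([min(a, b) for a, b in edges], dtype=np.intp)
    ej = np.array([max(a, b) for a, b in edges], dtype=np.intp)
    order = np.lexsort((ej, ei))
    return WeightedGraph(n_nodes, ei[order], ej[order], np.ones(len(edges)), 1.0)


def complete_graph(n, weight=1.0):
    iu, ju = np.triu_indices(n, k=1)
    return WeightedGraph(n, iu, ju, np.full(len(iu), weight), 1.0)


def nx_to_graph(G, n_nodes):
    edges = sorted((min(u, v), max(u, v)) for u, v in G.edges())
    ei = np.array([e[0] for e in edges], dtype=np.intp)
    ej = np.array([e[1] for e in edges], dtype=np.intp)
    return WeightedGraph(n_nodes, ei, ej, np.ones(len(edges)), 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
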