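import itertools

import networkx as nx
import numpy as np
import pytest

from genetriage import GeneList, InteractionNetwork, LiteratureMatrix, TermList


def ego_connectivity_oracle(graph: nx.Graph, node) -> float:
    """Brute force: enumerate all vertex pairs in {node} + neighbours."""
    ego = set(graph[node]) | {node}
    if len(ego) == 1:
        return 0.0
    present = sum(
        1 for u, v in itertools.combinations(sorted(ego), 2) if graph.has_edge(u, v)
    )
    possible = len(ego) * (len(ego) - 1) / 2
    return 100.0 * present / possible


def network_from_nx(graph: nx.Graph) -> InteractionNetwork:
    symbols = tuple(f"G{n}" for n in graph.nodes)
    relabeled = nx.relabel_nodes(graph, {n: f"G{n}" for n in graph.nodes})
    return InteractionNetwork(GeneList(symbols), relabeled)


@pytest.fixture
def triangle_network() -> InteractionNetwork:
    genes = GeneList(("A", "B", "C"))
    return InteractionNetwork.from_edges(genes, [("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def path_network() -> InteractionNetwork:
    genes = GeneList(("A", "B", "C"))
    return InteractionNetwork.from_edges(genes, [("A", "B"), ("B", "C")])


@pytest.fixture
def small_matrix() -> LiteratureMatrix:
    return LiteratureMatrix(
        genes=GeneList(("G1", "G2", "G3")),
        terms=TermList(("t1", "t2")),
        counts=np.array([[5, 0], [3, 10], [5, 2]]),
    )
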