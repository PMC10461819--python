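"""Shared fixtures and independent oracles.

The closeness oracle here deliberately avoids the package's own BFS: it
builds the dense adjacency matrix and runs scipy's shortest-path solver,
so agreement with the package is a genuine cross-check.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest
from scipy.sparse.csgraph import shortest_path


def oracle_closeness(g: nx.Graph) -> float:
    """Averaged per-component closeness via a dense all-pairs matrix.

    Mean of (n_reached)/(sum of distances to reached nodes) over all nodes
    with at least one neighbour; 0.0 if no such node exists.
    """
    nodes = list(g.nodes)
    if not nodes:
        return 0.0
    a = nx.to_numpy_array(g, nodelist=nodes, weight=None)
    d = shortest_path(a, method="D", unweighted=True)
    values = []
    for i, u in enumerate(nodes):
        if g.degree[u] == 0:
            continue
        row = d[i]
        reachable = np.isfinite(row) & (np.arange(len(nodes)) != i)
        values.append(reachable.sum() / row[reachable].sum())
    return float(np.mean(values)) if values else 0.0


def oracle_per_node_closeness(g: nx.Graph) -> dict:
    """networkx's closeness (Wasserman-Faust off) as a second, library
    route."""
    return nx.closeness_centrality(g, wf_improved=False)


@pytest.fixture
def bridged_cliques() -> nx.Graph:
    """Two complete 50-node components joined by exactly one bridge edge."""
    g = nx.disjoint_union(nx.complete_graph(50), nx.complete_graph(50))
    g.add_edge(0, 50)
    return g


@pytest.fixture
def mixed_graph() -> nx.Graph:
    """A network with heterogeneous components: a clique, a path, a sparse
    random component, a star, and small/singleton components."""
    g = nx.Graph()
    g = nx.disjoint_union_all(
        [
            nx.complete_graph(30),
            nx.path_graph(40),
            nx.gnm_random_graph(60, 90, seed=11),
            nx.star_graph(15),
            nx.cycle_graph(6),
        ]
    )
    g.add_nodes_from(range(1000, 1005))  # singletons
    return g
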