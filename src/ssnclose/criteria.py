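"""Network criteria for judging sequence similarity network (SSN) cutoffs.

The central quantity is the *averaged per-component closeness centrality*:
for a node ``u`` in a connected component of size ``n >= 2``,

    C(u) = (n - 1) / sum_v sp(u, v)

where ``sp`` counts edges on an unweighted shortest path and ``v`` runs over
the other nodes of u's component.  The network score is the arithmetic mean
of ``C(u)`` over all nodes with at least one neighbour (singletons are
excluded by default; an alternative mode scores them 0).  A score of 1
means every component of size >= 2 is a clique -- the signature of a clean
subfamily partition -- while sparsely bridged components drag the score
down.

The Wasserman-Faust correction, which rescales each ``C(u)`` by
``(n - 1) / (N - 1)`` with ``N`` the whole-graph node count, deliberately
penalises multi-component graphs.  Here multi-component graphs are the
*goal*, so the correction is off by default and exposed only for
comparison.

A small registry of classical whole-graph criteria (mean betweenness, mean
degree centrality, ...) is included so the closeness criterion can be
compared against the alternatives it was selected over.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Hashable, Iterable

import networkx as nx

__all__ = [
    "NodeCloseness",
    "CriterionResult",
    "connected_components",
    "closeness_by_component",
    "evaluate_criterion",
    "CRITERIA",
]

Node = Hashable


@dataclass(frozen=True)
class NodeCloseness:
    """Closeness value of one node, computed within its component."""

    node: Node
    value: float


@dataclass
class CriterionResult:
    """Outcome of evaluating one criterion on one graph."""

    name: str
    network_score: float
    n_components: int
    component_sizes: list[int] = field(default_factory=list)
    per_node: list[NodeCloseness] | None = None
    #: set when the score is defined by convention rather than computed
    #: (e.g. closeness of a graph with no edge at all).
    degenerate: bool = False


def connected_components(g: nx.Graph) -> list[set[Node]]:
    """Connected components of ``g`` as a list of node sets.

    Returned largest-first (ties broken by smallest member id, stringified)
    so downstream subfamily numbering is deterministic.
    """
    comps = [set(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), min(str(n) for n in c)))
    return comps


def _bfs_distance_sum(adj: dict[Node, list[Node]], source: Node) -> tuple[int, int]:
    """Sum of unweighted shortest-path distances from ``source`` to every
    reachable node, and the count of reached nodes (source excluded)."""
    seen = {source: 0}
    queue = deque([source])
    total = 0
    while queue:
        u = queue.popleft()
        d = seen[u]
        for v in adj[u]:
            if v not in seen:
                seen[v] = d + 1
                total += d + 1
                queue.append(v)
    return total, len(seen) - 1


def closeness_by_component(
    g: nx.Graph,
    wf_improved: bool = False,
    singleton_mode: str = "exclude",
) -> CriterionResult:
    """Averaged per-component closeness centrality of ``g``.

    Parameters
    ----------
    g:
        Simple undirected graph.
    wf_improved:
        Apply the Wasserman-Faust rescaling ``(n-1)/(N-1)`` to each node's
        closeness, where ``n`` is its component size and ``N`` the graph
        size.  Off by default: the correction penalises disconnected
        graphs, which is exactly what cutoff selection must not do.
    singleton_mode:
        ``"exclude"`` averages over nodes of degree >= 1 only (default);
        ``"zero"`` averages over all nodes with singletons contributing 0,
        which penalises heavily fragmented networks.

    Returns
    -------
    CriterionResult
        ``network_score`` in [0, 1] (wf off), with per-node values and the
        component-size histogram attached.
    """
    if singleton_mode not in ("exclude", "zero"):
        raise ValueError(f"singleton_mode must be 'exclude' or 'zero', got {singleton_mode!r}")

    comps = connected_components(g)
    sizes = [len(c) for c in comps]
    total_n = g.number_of_nodes()
    adj = {u: list(g.adj[u]) for u in g.nodes}

    per_node: list[NodeCloseness] = []
    values: list[float] = []
    n_singletons = 0
    for comp in comps:
        n = len(comp)
        if n == 1:
            n_singletons += 1
            if singleton_mode == "zero":
                node = next(iter(comp))
                per_node.append(NodeCloseness(node, 0.0))
                values.append(0.0)
            continue
        for u in comp:
            dist_sum, reached = _bfs_distance_sum(adj, u)
            # reached == n - 1 within a connected component
            c = reached / dist_sum
            if wf_improved and total_n > 1:
                c *= reached / (total_n - 1)
            per_node.append(NodeCloseness(u, c))
            values.append(c)

    if not values:
        warnings.warn(
            "graph has no connected node pair; closeness score defined as 0",
            stacklevel=2,
        )
        return CriterionResult(
            name="closeness_wf" if wf_improved else "closeness",
            network_score=0.0,
            n_components=len(comps),
            component_sizes=sizes,
            per_node=per_node,
            degenerate=True,
        )

    score = sum(values) / len(values)
    return CriterionResult(
        name="closeness_wf" if wf_improved else "closeness",
        network_score=score,
        n_components=len(comps),
        component_sizes=sizes,
        per_node=per_node,
    )


def _mean(values: Iterable[float], n: int) -> float:
    return sum(values) / n if n else 0.0


def _closeness_score(g: nx.Graph) -> float:
    return closeness_by_component(g, wf_improved=False).network_score


def _closeness_wf_score(g: nx.Graph) -> float:
    return closeness_by_component(g, wf_improved=True).network_score


def _degree_centrality_mean(g: nx.Graph) -> float:
    return _mean(nx.degree_centrality(g).values(), g.number_of_nodes())


def _betweenness_mean(g: nx.Graph) -> float:
    return _mean(nx.betweenness_centrality(g).values(), g.number_of_nodes())


def _harmonic_mean(g: nx.Graph) -> float:
    return _mean(nx.harmonic_centrality(g).values(), g.number_of_nodes())


def _clustering_mean(g: nx.Graph) -> float:
    return _mean(nx.clustering(g).values(), g.number_of_nodes())


def _average_degree(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    return 2 * g.number_of_edges() / n if n else 0.0


#: Registry of supported network criteria.  ``closeness`` is the criterion
#: this package exists for; the rest are the classical alternatives it is
#: compared against (several of which fail on singleton-heavy networks).
CRITERIA = {
    "closeness": _closeness_score,
    "closeness_wf": _closeness_wf_score,
    "degree_centrality_mean": _degree_centrality_mean,
    "betweenness_mean": _betweenness_mean,
    "harmonic_mean": _harmonic_mean,
    "clustering_mean": _clustering_mean,
    "n_components": nx.number_connected_components,
    "n_edges": nx.Graph.number_of_edges,
    "average_degree": _average_degree,
}


def evaluate_criterion(name: str, g: nx.Graph) -> CriterionResult:
    """Evaluate the registered criterion ``name`` on ``g``.

    Raises ``KeyError`` listing the valid names if ``name`` is unknown.
    """
    try:
        fn = CRITERIA[name]
    except KeyError:
        raise KeyError(
            f"unknown criterion {name!r}; valid names: {', '.join(sorted(CRITERIA))}"
        ) from None
    if name in ("closeness", "closeness_wf"):
        return closeness_by_component(g, wf_improved=(name == "closeness_wf"))
    comps = connected_components(g)
    return CriterionResult(
        name=name,
        network_score=float(fn(g)),
        n_components=len(comps),
        component_sizes=[len(c) for c in comps],
    )
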