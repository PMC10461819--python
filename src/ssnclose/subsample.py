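"""Shrink large SSNs for visualization.

Cytoscape chokes on components with tens of thousands of edges, and naive
node sampling warps network structure.  The scheme here is uniform edge
sampling with graph induction, applied per connected component so the
component count -- the biological signal -- is preserved exactly: draw
edges uniformly at random (without replacement) and keep both endpoints
until a target node count is reached, induce all original edges among the
kept nodes, then, if the induced sample fell apart, stitch it back
together along shortest paths of the original component.  Every node and
edge of the output exists in the input.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import networkx as nx

__all__ = ["SampleConfig", "subsample_component", "subsample_network"]


@dataclass(frozen=True)
class SampleConfig:
    """Subsampling parameters.

    ``min_keep``: components smaller than this are returned untouched, and
    no sampled component shrinks below it.  ``fraction``: target node
    fraction for sampled components (0.25 and 0.50 are the usual working
    values).  The target may be exceeded when reconnection paths pull in
    intermediate nodes; that is reported, not prevented.
    """

    min_keep: int = 10
    fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_keep < 1:
            raise ValueError("min_keep must be >= 1")
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")


def _reconnect(sample: nx.Graph, original: nx.Graph) -> None:
    """Reconnect a fallen-apart sample in place using shortest paths of the
    original component.

    The largest sub-component anchors; a multi-source BFS over the
    original graph finds the nearest node of any other sub-component, and
    the connecting path's nodes and edges (all original) are added.
    Repeats until connected.
    """
    while True:
        parts = sorted(nx.connected_components(sample), key=len, reverse=True)
        if len(parts) <= 1:
            return
        anchor = parts[0]
        others = set().union(*parts[1:])
        # BFS from all anchor nodes through the original component
        parent: dict = {u: None for u in anchor}
        frontier = list(anchor)
        hit = None
        while frontier and hit is None:
            nxt = []
            for u in frontier:
                for v in original.adj[u]:
                    if v in parent:
                        continue
                    parent[v] = u
                    if v in others:
                        hit = v
                        break
                    nxt.append(v)
                if hit is not None:
                    break
            frontier = nxt
        if hit is None:  # cannot happen for a connected original component
            raise RuntimeError("reconnection BFS exhausted a connected component")
        node = hit
        while parent[node] is not None:
            sample.add_edge(parent[node], node)
            node = parent[node]


def subsample_component(comp: nx.Graph, cfg: SampleConfig) -> nx.Graph:
    """Subsample one connected component.

    Components below ``cfg.min_keep`` nodes pass through unchanged.
    Otherwise edges are drawn uniformly without replacement (seeded),
    adding both endpoints, until ``max(min_keep, round(fraction * n))``
    nodes are collected; the sample is completed by graph induction and,
    if needed, shortest-path reconnection.  The output is always a
    connected subgraph of ``comp``.
    """
    if comp.number_of_nodes() == 0:
        return comp.copy()
    if not nx.is_connected(comp):
        raise ValueError("subsample_component expects a connected component")
    n = comp.number_of_nodes()
    if n < cfg.min_keep:
        return comp.copy()
    target = max(cfg.min_keep, round(cfg.fraction * n))
    if target >= n:
        return comp.copy()

    rng = random.Random(cfg.seed)
    edges = sorted(tuple(sorted(e)) for e in comp.edges)
    rng.shuffle(edges)
    kept: set = set()
    for u, v in edges:
        if len(kept) >= target:
            break
        kept.add(u)
        kept.add(v)
    sample: nx.Graph = comp.subgraph(kept).copy()  # induction: all original edges
    _reconnect(sample, comp)
    return sample


def subsample_network(net: nx.Graph, cfg: SampleConfig) -> nx.Graph:
    """Subsample every component of a network independently.

    The number of components is preserved exactly.  Per-component RNG
    streams are derived from ``cfg.seed`` and the component's smallest
    node id, so results do not depend on component iteration order.
    """
    out = nx.Graph()
    comps = sorted(nx.connected_components(net), key=lambda c: min(str(x) for x in c))
    for comp_nodes in comps:
        comp = net.subgraph(comp_nodes).copy()
        sub_seed = random.Random(f"{cfg.seed}:{min(str(x) for x in comp_nodes)}").randrange(2**31)
        sub = subsample_component(
            comp, SampleConfig(cfg.min_keep, cfg.fraction, sub_seed)
        )
        out = nx.union(out, sub)
    return out
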