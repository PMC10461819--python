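"""Artificial networks and synthetic similarity data.

Two kinds of fixtures live here:

* **Network collections** -- the benchmark used to choose a cutoff
  criterion.  A collection starts from two disconnected subnetworks
  (complete graphs, seeded G(n, m) random graphs, or bags of singletons)
  and adds one cross edge at a time until every cross pair is connected.
  Walking a criterion along the collection mimics walking an e-value
  threshold across a real family: a good criterion scores the clean
  two-component state and the fully merged state high, and sparsely
  bridged intermediates low.

* **Synthetic families** -- all-vs-all hit tables with a planted block
  structure (dense within-block similarity, a few weak bridges between
  blocks), written in the standard 12-column tabular hit format.  They
  give the sweep and optimum-detection code inputs whose correct answer
  is known by construction.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterator, Literal

import networkx as nx

from .criteria import evaluate_criterion
from .sweep import EdgeRecord

__all__ = [
    "SubnetworkSpec",
    "NetworkCollection",
    "make_subnetwork",
    "build_collection",
    "criterion_curve",
    "BENCHMARK_PAIRINGS",
    "FamilyBlock",
    "synthetic_family",
]

Kind = Literal["complete", "random", "singletons"]


@dataclass(frozen=True)
class SubnetworkSpec:
    """One artificial subnetwork: a clique, a G(n, m) draw, or singletons."""

    kind: Kind
    n: int
    m: int | None = None  # random kind only

    def __post_init__(self) -> None:
        if self.kind not in ("complete", "random", "singletons"):
            raise ValueError(f"unknown subnetwork kind {self.kind!r}")
        if self.n < 1:
            raise ValueError("subnetwork must have at least one node")
        if self.kind == "random":
            if self.m is None:
                raise ValueError("random subnetwork requires an edge count m")
            max_m = self.n * (self.n - 1) // 2
            if not 0 <= self.m <= max_m:
                raise ValueError(f"m={self.m} outside [0, {max_m}] for n={self.n}")
        elif self.m is not None:
            raise ValueError(f"m is only meaningful for kind='random', got kind={self.kind!r}")

    @classmethod
    def parse(cls, text: str) -> "SubnetworkSpec":
        """Parse ``"complete:50"``, ``"singletons:200"`` or ``"random:200:300"``."""
        parts = text.split(":")
        kind = parts[0]
        if kind == "random":
            if len(parts) != 3:
                raise ValueError(f"random spec needs 'random:N:M', got {text!r}")
            return cls("random", int(parts[1]), int(parts[2]))
        if len(parts) != 2:
            raise ValueError(f"spec needs 'kind:N', got {text!r}")
        return cls(kind, int(parts[1]))  # type: ignore[arg-type]


def make_subnetwork(spec: SubnetworkSpec, seed: int = 0, prefix: str = "a") -> nx.Graph:
    """Materialise one subnetwork with namespaced node ids ``{prefix}{i}``.

    The prefix keeps node ids of two subnetworks disjoint when they are
    combined into a collection.  The random kind draws a uniform simple
    graph with exactly ``m`` edges (seeded).
    """
    ids = [f"{prefix}{i}" for i in range(spec.n)]
    if spec.kind == "complete":
        g = nx.complete_graph(spec.n)
    elif spec.kind == "singletons":
        g = nx.empty_graph(spec.n)
    else:
        g = nx.gnm_random_graph(spec.n, spec.m, seed=seed)
    return nx.relabel_nodes(g, dict(zip(range(spec.n), ids)))


@dataclass
class NetworkCollection:
    """Ordered series of graphs over two fixed subnetworks.

    ``networks()`` yields ``n_a * n_b + 1`` graphs: the disconnected union
    first, then one extra cross edge per member.  Members are built lazily
    (a complete(200) x complete(200) collection has 40,001 members) from
    the stored cross-edge order, so iterating twice gives byte-identical
    graphs.
    """

    spec_a: SubnetworkSpec
    spec_b: SubnetworkSpec
    strategy: str
    seed: int
    cross_order: list[tuple[str, str]] = field(repr=False)
    _base: nx.Graph = field(repr=False)

    def __len__(self) -> int:
        return len(self.cross_order) + 1

    def networks(self) -> Iterator[nx.Graph]:
        g = self._base.copy()
        yield g.copy()
        for u, v in self.cross_order:
            g.add_edge(u, v)
            yield g.copy()

    def network_at(self, k: int) -> nx.Graph:
        """Graph with exactly ``k`` cross edges (k = 0 .. n_a*n_b)."""
        if not 0 <= k < len(self):
            raise IndexError(f"collection has members 0..{len(self) - 1}, got {k}")
        g = self._base.copy()
        g.add_edges_from(self.cross_order[:k])
        return g


def _cross_order(
    a_ids: list[str], b_ids: list[str], strategy: str, rng: random.Random,
    singles_first: bool,
) -> list[tuple[str, str]]:
    if strategy == "random":
        pairs = [(u, v) for u in a_ids for v in b_ids]
        rng.shuffle(pairs)
        return pairs
    # For the two singleton-specific strategies orient so the singleton
    # side drives the schedule.
    singles, others = (a_ids, b_ids) if singles_first else (b_ids, a_ids)
    order: list[tuple[str, str]] = []
    if strategy == "round_robin":
        # every singleton gets its first edge before any gets a second
        targets = {s: rng.sample(others, len(others)) for s in singles}
        sched = rng.sample(singles, len(singles))
        for round_i in range(len(others)):
            for s in sched:
                order.append((s, targets[s][round_i]))
    elif strategy == "exhaust_node":
        # one singleton is wired to every opposite node before the next starts
        for s in rng.sample(singles, len(singles)):
            for t in rng.sample(others, len(others)):
                order.append((s, t))
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    if singles_first:
        return order
    return [(t, s) for s, t in order]


def build_collection(
    a: SubnetworkSpec,
    b: SubnetworkSpec,
    strategy: str = "random",
    seed: int = 0,
) -> NetworkCollection:
    """Build a network collection from two subnetwork specs.

    ``strategy="random"`` adds cross edges in a seeded uniform random
    permutation of all ``n_a * n_b`` pairs.  ``"round_robin"`` and
    ``"exhaust_node"`` are only allowed when exactly one side is a
    singleton bag: round-robin gives every singleton its first edge before
    any receives a second; exhaust-node connects one singleton to every
    opposite node before starting the next.
    """
    if strategy not in ("random", "round_robin", "exhaust_node"):
        raise ValueError(f"unknown strategy {strategy!r}")
    singles_a = a.kind == "singletons"
    singles_b = b.kind == "singletons"
    if strategy != "random" and not (singles_a ^ singles_b):
        raise ValueError(
            f"strategy {strategy!r} requires exactly one singleton subnetwork "
            f"(got kinds {a.kind!r} and {b.kind!r})"
        )
    rng = random.Random(seed)
    ga = make_subnetwork(a, seed=rng.randrange(2**31), prefix="a")
    gb = make_subnetwork(b, seed=rng.randrange(2**31), prefix="b")
    base = nx.union(ga, gb)
    order = _cross_order(
        sorted(ga.nodes), sorted(gb.nodes), strategy, rng, singles_first=singles_a
    )
    return NetworkCollection(a, b, strategy, seed, order, base)


def criterion_curve(
    collection: NetworkCollection, name: str = "closeness"
) -> list[tuple[int, float]]:
    """Evaluate a registered criterion on every member of a collection.

    Returns ``(cross_edge_count, score)`` pairs in collection order.
    """
    return [
        (k, evaluate_criterion(name, g).network_score)
        for k, g in enumerate(collection.networks())
    ]


#: The subnetwork pairings used as the criterion-selection benchmark:
#: a complete graph of 50 against the full range of partner topologies,
#: and singleton bags against random graphs (all three strategies apply
#: to the singleton pairings).
BENCHMARK_PAIRINGS: list[tuple[SubnetworkSpec, SubnetworkSpec]] = [
    (SubnetworkSpec("complete", 50), SubnetworkSpec("singletons", 1)),
    (SubnetworkSpec("complete", 50), SubnetworkSpec("singletons", 50)),
    (SubnetworkSpec("complete", 50), SubnetworkSpec("singletons", 200)),
    (SubnetworkSpec("complete", 50), SubnetworkSpec("complete", 3)),
    (SubnetworkSpec("complete", 50), SubnetworkSpec("complete", 50)),
    (SubnetworkSpec("complete", 50), SubnetworkSpec("complete", 200)),
    (SubnetworkSpec("complete", 50), SubnetworkSpec("random", 50, 250)),
    (SubnetworkSpec("complete", 50), SubnetworkSpec("random", 50, 500)),
    (SubnetworkSpec("complete", 50), SubnetworkSpec("random", 200, 500)),
    (SubnetworkSpec("complete", 50), SubnetworkSpec("random", 200, 1000)),
    (SubnetworkSpec("complete", 50), SubnetworkSpec("random", 200, 2000)),
    (SubnetworkSpec("complete", 50), SubnetworkSpec("random", 200, 3000)),
    (SubnetworkSpec("complete", 50), SubnetworkSpec("random", 200, 4000)),
    (SubnetworkSpec("singletons", 50), SubnetworkSpec("random", 200, 500)),
    (SubnetworkSpec("singletons", 200), SubnetworkSpec("random", 200, 500)),
]


@dataclass(frozen=True)
class FamilyBlock:
    """One dense block of a synthetic protein family.

    ``intra_exponent_range`` gives the -log10 e-value range for
    within-block hits (drawn uniformly); the block is fully connected
    within itself, mimicking a tight subfamily.
    """

    n: int
    intra_exponent_range: tuple[float, float] = (40.0, 80.0)


def synthetic_family(
    blocks: list[FamilyBlock],
    bridges: list[tuple[int, int, float, int]],
    seed: int = 0,
    n_orphans: int = 0,
) -> tuple[list[EdgeRecord], set[str]]:
    """Generate a synthetic family's aggregated hit table.

    Parameters
    ----------
    blocks:
        Dense blocks; block ``i`` gets sequence ids ``B{i}_{j}``.
    bridges:
        ``(block_i, block_j, exponent, n_pairs)`` tuples: ``n_pairs``
        cross-block hits at exactly ``-log10(evalue) = exponent``.  An
        e-value sweep disconnects blocks i and j one step past
        ``floor(exponent)``, so the planted split cutoffs are known.
    n_orphans:
        Sequences with no hits at all; they stay singletons at every
        cutoff.

    Returns
    -------
    (records, ids):
        Aggregated undirected edge records plus the full id universe.
    """
    rng = random.Random(seed)
    ids: set[str] = set()
    block_ids: list[list[str]] = []
    records: list[EdgeRecord] = []
    for i, blk in enumerate(blocks):
        members = [f"B{i}_{j}" for j in range(blk.n)]
        block_ids.append(members)
        ids.update(members)
        lo, hi = blk.intra_exponent_range
        for x in range(blk.n):
            for y in range(x + 1, blk.n):
                exp = rng.uniform(lo, hi)
                records.append(
                    EdgeRecord.make(
                        members[x], members[y],
                        neg_log10_evalue=exp,
                        bitscore=round(2.0 * exp + 50.0, 1),
                        identity=round(rng.uniform(40.0, 95.0), 1),
                    )
                )
    for bi, bj, exponent, n_pairs in bridges:
        pairs = [(u, v) for u in block_ids[bi] for v in block_ids[bj]]
        for u, v in rng.sample(pairs, n_pairs):
            records.append(
                EdgeRecord.make(
                    u, v,
                    neg_log10_evalue=float(exponent),
                    bitscore=round(2.0 * exponent + 50.0, 1),
                    identity=round(rng.uniform(25.0, 40.0), 1),
                )
            )
    ids.update(f"orphan_{k}" for k in range(n_orphans))
    return records, ids
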