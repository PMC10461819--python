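"""Build sequence similarity networks from all-vs-all hits and sweep cutoffs.

Hits arrive in the de-facto 12-column tabular alignment format (query,
subject, %identity, alignment length, mismatches, gap opens, qstart, qend,
sstart, send, e-value, bitscore).  Directed hits are aggregated into one
undirected :class:`EdgeRecord` per sequence pair, keeping the most
significant e-value and the highest bitscore over all HSPs in either
direction; sequences with no hit at all become singleton nodes.

Significance is handled in -log10 space throughout.  A reported e-value of
``0.0`` -- the double-precision underflow that affects long domains below
about 1e-308 -- maps to ``+inf`` and therefore passes every e-value cutoff;
thresholding compares exponents, never raw floats.  For families where
underflow swallows the whole dynamic range, a bitscore-mode sweep over a
user-supplied or quantile-derived grid is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import networkx as nx
import numpy as np
import pandas as pd

from .criteria import evaluate_criterion

__all__ = [
    "EdgeRecord",
    "SweepConfig",
    "ThresholdedNetwork",
    "CriterionProfile",
    "parse_hits",
    "write_hits",
    "fasta_ids",
    "build_network_at",
    "sweep",
    "bitscore_grid_from_quantiles",
]


@dataclass(frozen=True)
class EdgeRecord:
    """One aggregated undirected similarity relation between two sequences."""

    id_a: str
    id_b: str
    best_neg_log10_evalue: float  # +inf for a reported e-value of 0.0
    best_bitscore: float
    best_identity: float

    def __post_init__(self) -> None:
        if self.id_a == self.id_b:
            raise ValueError(f"self relation not allowed: {self.id_a!r}")
        if self.id_a > self.id_b:
            raise ValueError("EdgeRecord ids must be in canonical (sorted) order")

    @classmethod
    def make(
        cls,
        u: str,
        v: str,
        neg_log10_evalue: float,
        bitscore: float = 0.0,
        identity: float = 0.0,
    ) -> "EdgeRecord":
        a, b = sorted((u, v))
        return cls(a, b, float(neg_log10_evalue), float(bitscore), float(identity))


def _neg_log10(evalue: float) -> float:
    if evalue < 0:
        raise ValueError(f"negative e-value {evalue!r}")
    if evalue == 0.0:
        return math.inf
    return -math.log10(evalue)


def parse_hits(
    source: str | IO[str],
    id_universe: set[str] | None = None,
) -> tuple[list[EdgeRecord], set[str]]:
    """Parse a 12-column tabular hit stream into aggregated edge records.

    Self-hits are dropped; reciprocal and duplicate rows collapse to one
    record per unordered pair keeping the best e-value / bitscore /
    identity seen in any direction.  Ids present in ``id_universe`` but in
    no hit are registered as isolated nodes.

    Returns ``(records, ids)`` where ``ids`` covers every sequence seen.
    Raises ``ValueError`` with the 1-based line number on a malformed row.
    """
    best: dict[tuple[str, str], list[float]] = {}
    ids: set[str] = set(id_universe) if id_universe else set()
    handle = open(source) if isinstance(source, str) else source
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(
                    f"line {lineno}: expected 12 tab-separated columns, got {len(cols)}"
                )
            q, s = cols[0], cols[1]
            try:
                identity = float(cols[2])
                evalue = float(cols[10])
                bitscore = float(cols[11])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
            try:
                sig = _neg_log10(evalue)
            except ValueError:
                raise ValueError(f"line {lineno}: negative e-value {evalue}") from None
            ids.add(q)
            ids.add(s)
            if q == s:
                continue
            key = (q, s) if q < s else (s, q)
            cur = best.get(key)
            if cur is None:
                best[key] = [sig, bitscore, identity]
            else:
                cur[0] = max(cur[0], sig)
                cur[1] = max(cur[1], bitscore)
                cur[2] = max(cur[2], identity)
    finally:
        if isinstance(source, str):
            handle.close()
    records = [
        EdgeRecord(a, b, sig, bit, ident)
        for (a, b), (sig, bit, ident) in sorted(best.items())
    ]
    return records, ids


def write_hits(records: Iterable[EdgeRecord], path: str | IO[str]) -> None:
    """Write edge records as 12-column tabular rows (one direction each).

    Positional columns not carried by :class:`EdgeRecord` (alignment
    length, mismatches, coordinates) are written as 0 placeholders; an
    infinite significance round-trips as e-value ``0.0``.
    """
    handle = open(path, "w") if isinstance(path, str) else path
    try:
        for r in records:
            evalue = 0.0 if math.isinf(r.best_neg_log10_evalue) else 10 ** (-r.best_neg_log10_evalue)
            handle.write(
                f"{r.id_a}\t{r.id_b}\t{r.best_identity}\t0\t0\t0\t0\t0\t0\t0"
                f"\t{evalue:.3g}\t{r.best_bitscore}\n"
            )
    finally:
        if isinstance(path, str):
            handle.close()


def fasta_ids(path: str | IO[str]) -> set[str]:
    """Sequence id universe from a FASTA file (first whitespace-delimited
    header token)."""
    from Bio import SeqIO

    return {rec.id for rec in SeqIO.parse(path, "fasta")}


@dataclass
class ThresholdedNetwork:
    """An SSN at one cutoff: the graph plus the cutoff that produced it."""

    graph: nx.Graph
    cutoff: float
    mode: str = "evalue"  # cutoff is an exponent (evalue) or a bitscore


def build_network_at(
    records: Iterable[EdgeRecord],
    ids: set[str],
    cutoff: float,
    mode: str = "evalue",
) -> ThresholdedNetwork:
    """SSN at one cutoff: nodes are exactly ``ids``; an edge survives iff
    ``best_neg_log10_evalue >= cutoff`` (e-value mode, i.e. e-value <=
    10^-cutoff) or ``best_bitscore >= cutoff`` (bitscore mode)."""
    if not ids:
        raise ValueError("empty id universe")
    if mode not in ("evalue", "bitscore"):
        raise ValueError(f"mode must be 'evalue' or 'bitscore', got {mode!r}")
    g = nx.Graph()
    g.add_nodes_from(ids)
    for r in records:
        value = r.best_neg_log10_evalue if mode == "evalue" else r.best_bitscore
        if value >= cutoff:
            g.add_edge(r.id_a, r.id_b)
    return ThresholdedNetwork(g, cutoff, mode)


@dataclass
class SweepConfig:
    """Cutoff grid for a sweep.

    E-value mode walks exponents ``exponent_start .. exponent_end`` (i.e.
    cutoffs 10^-start down to 10^-end) in integer steps; bitscore mode
    walks ``bitscore_grid`` in increasing order.  The sweep stops early
    once the network disintegrates past ``max_components``.
    """

    exponent_start: int = 5
    exponent_end: int = 160
    step: int = 1
    mode: str = "evalue"
    bitscore_grid: list[float] | None = None
    max_components: int = 1000

    def __post_init__(self) -> None:
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.exponent_start > self.exponent_end:
            raise ValueError("exponent_start must be <= exponent_end")
        if self.mode not in ("evalue", "bitscore"):
            raise ValueError(f"mode must be 'evalue' or 'bitscore', got {self.mode!r}")
        if self.mode == "bitscore" and not self.bitscore_grid:
            raise ValueError("bitscore mode requires a bitscore_grid")

    def cutoffs(self) -> Iterator[float]:
        if self.mode == "evalue":
            yield from range(self.exponent_start, self.exponent_end + 1, self.step)
        else:
            yield from sorted(self.bitscore_grid)  # type: ignore[arg-type]


@dataclass
class CriterionProfile:
    """Per-cutoff criterion trace of a sweep.

    ``table`` has one row per evaluated cutoff with columns ``cutoff``,
    ``score``, ``n_components``, ``n_singletons``, ``n_components_ge_min``;
    ``component_sizes[i]`` holds the full size multiset for row ``i``.
    """

    table: pd.DataFrame
    component_sizes: list[list[int]]
    criterion: str
    mode: str
    min_size: int

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(
        cls, path: str, criterion: str = "closeness", mode: str = "evalue",
        min_size: int = 10,
    ) -> "CriterionProfile":
        table = pd.read_csv(path, sep="\t")
        required = {"cutoff", "score", "n_components"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"profile missing columns: {sorted(missing)}")
        return cls(table, [], criterion, mode, min_size)


def sweep(
    records: Iterable[EdgeRecord],
    ids: set[str],
    cfg: SweepConfig | None = None,
    criterion: str = "closeness",
    min_size: int = 10,
) -> CriterionProfile:
    """Walk the cutoff grid and evaluate the criterion at every cutoff.

    The sweep terminates after the first cutoff where the component count
    exceeds ``cfg.max_components`` or the edge set empties (everything
    after would stay fully disintegrated).
    """
    cfg = cfg or SweepConfig()
    records = list(records)
    rows = []
    all_sizes: list[list[int]] = []
    for cutoff in cfg.cutoffs():
        net = build_network_at(records, ids, cutoff, mode=cfg.mode)
        res = evaluate_criterion(criterion, net.graph)
        sizes = res.component_sizes
        n_single = sum(1 for s in sizes if s == 1)
        rows.append(
            {
                "cutoff": cutoff,
                "score": res.network_score,
                "n_components": res.n_components,
                "n_singletons": n_single,
                "n_components_ge_min": sum(1 for s in sizes if s >= min_size),
            }
        )
        all_sizes.append(sizes)
        if res.n_components > cfg.max_components or net.graph.number_of_edges() == 0:
            break
    table = pd.DataFrame(rows)
    return CriterionProfile(table, all_sizes, criterion, cfg.mode, min_size)


def bitscore_grid_from_quantiles(
    records: Iterable[EdgeRecord], n: int = 50
) -> list[float]:
    """Evenly spaced quantiles of the observed bitscores, for bitscore-mode
    sweeps when no explicit grid is given."""
    scores = np.array([r.best_bitscore for r in records], dtype=float)
    if scores.size == 0:
        raise ValueError("no records to derive a bitscore grid from")
    qs = np.linspace(0.0, 1.0, n)
    return sorted(set(np.quantile(scores, qs).tolist()))
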