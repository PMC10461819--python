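"""Reconstruct full domain sequences from fragmented HMM-search hits.

Profile HMM searches report local alignments, so a single domain in a
divergent protein often surfaces as several fragments.  This module chains
such fragments back into one domain per (sequence, HMM) pair, applies the
length sanity filters used when preparing modular enzyme families for
network analysis, resolves proteins matched by several HMMs to a single
domain, and slices the assembled coordinates out of the protein FASTA.

Merge rules for two consecutive fragments (sorted by sequence start):

i.   their sequence start coordinates differ by more than 20 residues, and
     so do their end coordinates (otherwise they are near-duplicate HSPs
     of the same region, not pieces of one domain);
ii.  the gap between the first fragment's end and the second's start is at
     most 200 residues;
iii. their profile (HMM) coordinates overlap by at most 30 positions.

A fragment failing any rule starts a new assembly.  Fragments whose
sequence intervals overlap are never merged -- overlapping local hits are
alternative alignments of the same stretch, not adjacent pieces.

Coordinates are 1-based inclusive throughout (the HMMER convention);
alignment coordinates are used, not envelope coordinates.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

__all__ = [
    "DomainHit",
    "AssembledDomain",
    "parse_domtblout",
    "filter_hits",
    "assemble_fragments",
    "assemble_all",
    "length_filter",
    "resolve_multi_hmm",
    "extract_sequences",
]

EVALUE_CUTOFF = 1e-4  # strict: hits at exactly 1e-4 are dropped
MAX_START_END_PROXIMITY = 20  # rule i: both start and end separation must exceed this
MAX_SEQ_GAP = 200  # rule ii
MAX_HMM_OVERLAP = 30  # rule iii


@dataclass(frozen=True)
class DomainHit:
    """One per-domain hit from a profile HMM search."""

    seq_id: str
    hmm_name: str
    hmm_length: int
    seq_from: int
    seq_to: int
    hmm_from: int
    hmm_to: int
    i_evalue: float

    def __post_init__(self) -> None:
        if not (1 <= self.seq_from <= self.seq_to):
            raise ValueError(f"bad sequence coordinates {self.seq_from}-{self.seq_to}")
        if not (1 <= self.hmm_from <= self.hmm_to):
            raise ValueError(f"bad profile coordinates {self.hmm_from}-{self.hmm_to}")


@dataclass
class AssembledDomain:
    """A domain reconstructed from one or more fragments."""

    seq_id: str
    hmm_name: str
    seq_from: int
    seq_to: int
    fragments: list[DomainHit] = field(default_factory=list)
    length_flag: str = "ok"  # ok | short_discarded | outlier_flagged

    @property
    def length(self) -> int:
        return self.seq_to - self.seq_from + 1


def parse_domtblout(source: str | IO[str]) -> list[DomainHit]:
    """Parse HMMER3 ``--domtblout`` output (hmmscan orientation: target =
    HMM profile, query = protein sequence)."""
    handle = open(source) if isinstance(source, str) else source
    hits: list[DomainHit] = []
    try:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 22:
                raise ValueError(f"line {lineno}: expected >=22 columns, got {len(cols)}")
            try:
                hits.append(
                    DomainHit(
                        seq_id=cols[3],
                        hmm_name=cols[0],
                        hmm_length=int(cols[2]),
                        seq_from=int(cols[17]),
                        seq_to=int(cols[18]),
                        hmm_from=int(cols[15]),
                        hmm_to=int(cols[16]),
                        i_evalue=float(cols[12]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
    finally:
        if isinstance(source, str):
            handle.close()
    return hits


def filter_hits(hits: Iterable[DomainHit], cutoff: float = EVALUE_CUTOFF) -> list[DomainHit]:
    """Keep hits with independent e-value strictly below ``cutoff``."""
    return [h for h in hits if h.i_evalue < cutoff]


def _can_merge(cur: DomainHit, nxt: DomainHit) -> bool:
    if nxt.seq_from <= cur.seq_to:  # overlapping sequence intervals: never merge
        return False
    if abs(nxt.seq_from - cur.seq_from) <= MAX_START_END_PROXIMITY:  # rule i (starts)
        return False
    if abs(nxt.seq_to - cur.seq_to) <= MAX_START_END_PROXIMITY:  # rule i (ends)
        return False
    if nxt.seq_from - cur.seq_to > MAX_SEQ_GAP:  # rule ii
        return False
    if cur.hmm_to - nxt.hmm_from + 1 > MAX_HMM_OVERLAP:  # rule iii
        return False
    return True


def assemble_fragments(hits: Sequence[DomainHit]) -> list[AssembledDomain]:
    """Chain the fragments of one (sequence, HMM) pair, greedily left to
    right; a fragment that cannot extend the current chain starts a new
    assembly.  Input need not be sorted."""
    if not hits:
        return []
    seq_ids = {h.seq_id for h in hits}
    hmms = {h.hmm_name for h in hits}
    if len(seq_ids) > 1 or len(hmms) > 1:
        raise ValueError("assemble_fragments expects hits of one sequence and one HMM")
    ordered = sorted(hits, key=lambda h: (h.seq_from, h.seq_to))
    assemblies: list[list[DomainHit]] = [[ordered[0]]]
    for h in ordered[1:]:
        if _can_merge(assemblies[-1][-1], h):
            assemblies[-1].append(h)
        else:
            assemblies.append([h])
    return [
        AssembledDomain(
            seq_id=frags[0].seq_id,
            hmm_name=frags[0].hmm_name,
            seq_from=frags[0].seq_from,
            seq_to=frags[-1].seq_to,
            fragments=list(frags),
        )
        for frags in assemblies
    ]


def assemble_all(hits: Iterable[DomainHit]) -> list[AssembledDomain]:
    """Group filtered hits by (sequence, HMM) and assemble each group."""
    groups: dict[tuple[str, str], list[DomainHit]] = {}
    for h in hits:
        groups.setdefault((h.seq_id, h.hmm_name), []).append(h)
    out: list[AssembledDomain] = []
    for key in sorted(groups):
        out.extend(assemble_fragments(groups[key]))
    return out


def length_filter(
    domains: Iterable[AssembledDomain],
    hmm_lengths: Mapping[str, int],
    n_sd: float = 3.0,
) -> list[AssembledDomain]:
    """Apply the two length sanity checks, setting ``length_flag``.

    A domain shorter than half its HMM's length (strictly) is marked
    ``short_discarded``.  Over the retained population, domains outside
    mean +/- ``n_sd`` sample standard deviations are marked
    ``outlier_flagged`` -- kept, but surfaced for manual inspection of
    gene-model issues.
    """
    domains = list(domains)
    retained: list[AssembledDomain] = []
    for d in domains:
        hmm_len = hmm_lengths[d.hmm_name]
        if d.length < hmm_len / 2:
            d.length_flag = "short_discarded"
        else:
            d.length_flag = "ok"
            retained.append(d)
    if len(retained) >= 2:
        lengths = [d.length for d in retained]
        mean = statistics.fmean(lengths)
        sd = statistics.stdev(lengths)
        lo, hi = mean - n_sd * sd, mean + n_sd * sd
        for d in retained:
            if not (lo <= d.length <= hi):
                d.length_flag = "outlier_flagged"
    return domains


def resolve_multi_hmm(
    domains: Iterable[AssembledDomain],
    hmm_order: Sequence[str],
    log: list[str] | None = None,
) -> dict[str, AssembledDomain]:
    """One domain per sequence when several HMMs matched: the longest wins;
    an exact length tie goes to the HMM listed first in ``hmm_order`` (the
    decision is appended to ``log`` when given)."""
    rank = {name: i for i, name in enumerate(hmm_order)}
    best: dict[str, AssembledDomain] = {}
    for d in domains:
        if d.hmm_name not in rank:
            raise ValueError(f"HMM {d.hmm_name!r} not in configured order {list(hmm_order)}")
        cur = best.get(d.seq_id)
        if cur is None:
            best[d.seq_id] = d
            continue
        if d.length > cur.length:
            best[d.seq_id] = d
        elif d.length == cur.length and rank[d.hmm_name] < rank[cur.hmm_name]:
            if log is not None:
                log.append(
                    f"{d.seq_id}: length tie ({d.length}) between "
                    f"{cur.hmm_name} and {d.hmm_name}; kept {d.hmm_name} "
                    "(first in configured order)"
                )
            best[d.seq_id] = d
        elif d.length == cur.length and log is not None:
            log.append(
                f"{d.seq_id}: length tie ({d.length}) between "
                f"{cur.hmm_name} and {d.hmm_name}; kept {cur.hmm_name} "
                "(first in configured order)"
            )
    return best


def extract_sequences(
    domains: Iterable[AssembledDomain],
    fasta: str | IO[str],
) -> list[tuple[str, str]]:
    """Slice assembled domain subsequences out of a protein FASTA.

    Returns ``(record_id, subsequence)`` pairs named
    ``seq_id/seq_from-seq_to``; ids are the first whitespace-delimited
    header token.  Raises ``KeyError``/``ValueError`` naming the offending
    record on a missing id or out-of-range coordinates.
    """
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(fasta, "fasta")}
    out: list[tuple[str, str]] = []
    for d in domains:
        if d.seq_id not in seqs:
            raise KeyError(f"sequence {d.seq_id!r} not found in FASTA")
        seq = seqs[d.seq_id]
        if d.seq_to > len(seq):
            raise ValueError(
                f"{d.seq_id}: domain {d.seq_from}-{d.seq_to} exceeds sequence length {len(seq)}"
            )
        out.append((f"{d.seq_id}/{d.seq_from}-{d.seq_to}", seq[d.seq_from - 1 : d.seq_to]))
    return out
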