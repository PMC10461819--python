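"""Optimum detection on criterion profiles and subfamily assignment.

An "optimum" on a closeness profile is a cutoff where the score jumps up
*because* a sparsely bridged component finally splits: the bridge edges
drop out, the average shortest path inside each half collapses, and the
score recovers.  Candidates are therefore cutoffs where the score strictly
increases relative to the previous cutoff and the component count rises at
the same step; the global maximum is always reported too.  The tool ranks
candidates and surfaces the evidence (score, drop depth, subfamily counts,
unclassified sequences) -- it never auto-picks a single cutoff, since
several optima can be biologically meaningful and the curator decides.

Subfamilies at a chosen cutoff are the connected components with at least
``min_size`` members, numbered 1..k by descending size; everything smaller
is pooled as unclassified (label 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .criteria import connected_components
from .sweep import CriterionProfile, ThresholdedNetwork

__all__ = [
    "OptimumCandidate",
    "SubfamilyAssignment",
    "find_optima",
    "assign_subfamilies",
    "summarize_annotations",
]


@dataclass
class OptimumCandidate:
    """One candidate optimal cutoff on a criterion profile."""

    cutoff: float
    score_at: float
    preceding_minimum: float
    drop_depth: float  # score_at - preceding_minimum
    n_components_ge_min: int
    n_unclassified: int
    is_global: bool
    #: "split", "score_neutral_split", or "no_split_events" (degenerate
    #: profile with no split at all; the global maximum is still reported)
    kind: str = "split"


def _row_unclassified(sizes: Sequence[int], min_size: int) -> int:
    return sum(s for s in sizes if s < min_size)


def find_optima(profile: CriterionProfile, min_size: int | None = None) -> list[OptimumCandidate]:
    """Detect candidate optimal cutoffs on a criterion profile.

    A candidate is any cutoff where the score strictly increases from the
    previous cutoff *and* the component count increases at that step (a
    split event).  A split with an unchanged score is reported too, marked
    ``score_neutral_split``.  The global maximum (ties broken to the least
    stringent cutoff) is always included and flagged ``is_global``.

    Candidates are ranked by score descending, then by drop depth (score
    minus the trough preceding the jump) descending, then least stringent
    first.  ``n_unclassified`` counts sequences in components below
    ``min_size`` at that cutoff (0 when the profile carries no component
    sizes, e.g. when loaded from a bare TSV).
    """
    if min_size is None:
        min_size = profile.min_size
    t = profile.table
    if len(t) < 2:
        raise ValueError("profile must have at least 2 rows to detect optima")
    scores = t["score"].to_numpy()
    comps = t["n_components"].to_numpy()
    cutoffs = t["cutoff"].to_numpy()
    have_sizes = len(profile.component_sizes) == len(t)

    def ge_min(i: int) -> int:
        if "n_components_ge_min" in t.columns:
            return int(t["n_components_ge_min"].iloc[i])
        if have_sizes:
            return sum(1 for s in profile.component_sizes[i] if s >= min_size)
        return 0

    def unclassified(i: int) -> int:
        if have_sizes:
            return _row_unclassified(profile.component_sizes[i], min_size)
        return 0

    def trough_before(i: int) -> float:
        # walk back through the monotone descent leading into the jump
        j = i - 1
        while j > 0 and scores[j - 1] >= scores[j]:
            j -= 1
        return float(scores[i - 1 : i].min() if j == i - 1 else scores[j:i].min())

    global_idx = int(scores.argmax())  # argmax takes the first (least stringent) tie
    candidates: list[OptimumCandidate] = []
    seen_idx: set[int] = set()
    for i in range(1, len(t)):
        if comps[i] <= comps[i - 1]:
            continue
        if scores[i] > scores[i - 1]:
            kind = "split"
        elif scores[i] == scores[i - 1]:
            kind = "score_neutral_split"
        else:
            continue
        trough = trough_before(i)
        candidates.append(
            OptimumCandidate(
                cutoff=float(cutoffs[i]),
                score_at=float(scores[i]),
                preceding_minimum=trough,
                drop_depth=float(scores[i]) - trough,
                n_components_ge_min=ge_min(i),
                n_unclassified=unclassified(i),
                is_global=(i == global_idx),
                kind=kind,
            )
        )
        seen_idx.add(i)

    if global_idx not in seen_idx:
        kind = "split" if candidates else "no_split_events"
        candidates.append(
            OptimumCandidate(
                cutoff=float(cutoffs[global_idx]),
                score_at=float(scores[global_idx]),
                preceding_minimum=(
                    trough_before(global_idx) if global_idx > 0 else float(scores[0])
                ),
                drop_depth=(
                    float(scores[global_idx]) - trough_before(global_idx)
                    if global_idx > 0
                    else 0.0
                ),
                n_components_ge_min=ge_min(global_idx),
                n_unclassified=unclassified(global_idx),
                is_global=True,
                kind=kind,
            )
        )

    candidates.sort(key=lambda c: (-c.score_at, -c.drop_depth, c.cutoff))
    return candidates


@dataclass
class SubfamilyAssignment:
    """Sequence id -> subfamily label (1..k by descending size, 0 =
    unclassified)."""

    labels: dict[str, int]
    min_size: int
    cutoff: float | None = None

    @property
    def n_subfamilies(self) -> int:
        return max(self.labels.values(), default=0)

    def members(self, label: int) -> set[str]:
        return {s for s, l in self.labels.items() if l == label}

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for l in self.labels.values():
            out[l] = out.get(l, 0) + 1
        return out

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("sequence_id\tsubfamily\n")
            for seq in sorted(self.labels):
                fh.write(f"{seq}\t{self.labels[seq]}\n")


def assign_subfamilies(net: ThresholdedNetwork, min_size: int) -> SubfamilyAssignment:
    """Label the components of an SSN as subfamilies.

    Components with at least ``min_size`` members get labels 1..k by
    descending size (size ties broken by the lexicographically smallest
    member id); every other sequence is labelled 0.  ``min_size`` is a
    curator decision and must be passed explicitly.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    comps = connected_components(net.graph)  # sorted largest-first, tie by min id
    labels: dict[str, int] = {str(n): 0 for n in net.graph.nodes}
    k = 0
    for comp in comps:
        if len(comp) < min_size:
            continue
        k += 1
        for node in comp:
            labels[str(node)] = k
    return SubfamilyAssignment(labels, min_size, cutoff=net.cutoff)


def summarize_annotations(
    assignment: SubfamilyAssignment,
    annotations: Mapping[str, str | Sequence[str]],
    sep: str = ";",
) -> tuple[pd.DataFrame, list[str]]:
    """Tabulate annotations (EC numbers, taxa, ...) per subfamily.

    ``annotations`` maps sequence id to a label or a multi-label string
    (``"3.2.1.4;3.2.1.8"`` counts once under each value).  Returns one row
    per (subfamily, annotation value) plus a size/coverage row per
    subfamily with a blank annotation value, and the list of annotation
    ids absent from the assignment (reported, never fatal).
    """
    unknown = sorted(set(annotations) - set(assignment.labels))
    per_label: dict[int, dict[str, int]] = {}
    annotated: dict[int, int] = {}
    for seq, label in assignment.labels.items():
        ann = annotations.get(seq)
        if ann is None:
            continue
        values = ann if not isinstance(ann, str) else [v.strip() for v in ann.split(sep)]
        values = [v for v in values if v]
        if not values:
            continue
        annotated[label] = annotated.get(label, 0) + 1
        counts = per_label.setdefault(label, {})
        for v in set(values):
            counts[v] = counts.get(v, 0) + 1

    sizes = assignment.sizes()
    rows = []
    for label in sorted(sizes):
        size = sizes[label]
        n_ann = annotated.get(label, 0)
        rows.append(
            {
                "subfamily": label,
                "size": size,
                "annotation": "",
                "count": n_ann,
                "fraction_annotated": n_ann / size if size else 0.0,
            }
        )
        for value, count in sorted(
            per_label.get(label, {}).items(), key=lambda kv: (-kv[1], kv[0])
        ):
            rows.append(
                {
                    "subfamily": label,
                    "size": size,
                    "annotation": value,
                    "count": count,
                    "fraction_annotated": count / size if size else 0.0,
                }
            )
    return pd.DataFrame(rows), unknown
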