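"""Domain-architecture consolidation and fragment decomposition.

Domain annotations (curated Pfam-style intervals plus homology-derived
hits) are merged, reduced for overlap by a greedy longest-first rule,
and used to split each protein into inter-domain fragments.  Each
fragment is extended by a buffer (default 10 residues) into the flanking
domain(s) — domain edge annotations are frequently imprecise — and
classified as N-terminal, internal (domains on both flanks) or
C-terminal.  Fragments are scored independently for prion-like
composition to count multiple prion-like domains per protein.

Coordinates are 1-based inclusive throughout (Pfam/InterPro convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .prion import PrionScore

DEFAULT_BUFFER = 10
_SOURCE_RANK = {"curated": 0, "homology": 1}


@dataclass(frozen=True)
class DomainInterval:
    seq_id: str
    start: int        # 1-based inclusive
    end: int
    kind: str = "RRM"           # "RRM" | "other"
    source: str = "curated"     # "curated" | "homology"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid coordinates for {self.seq_id}: "
                f"start={self.start}, end={self.end} (1-based inclusive required)"
            )
        if self.source not in _SOURCE_RANK:
            raise ValueError(f"unknown source {self.source!r} for {self.seq_id}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "DomainInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass(frozen=True)
class Fragment:
    seq_id: str
    start: int        # buffered, 1-based inclusive, clipped to sequence
    end: int
    position_class: str  # "n_terminal" | "internal" | "c_terminal"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def reduce_overlaps(
    annotations: Sequence[DomainInterval],
) -> tuple[list[DomainInterval], list[DomainInterval]]:
    """Greedy longest-first overlap reduction.

    Intervals are sorted by decreasing length and walked in order; an
    interval is kept iff it shares no residue with any already-kept
    interval on the same sequence, otherwise flagged.  Equal lengths tie
    -break by earlier start, curated before homology, then input order.
    The input is never mutated.
    """
    order = sorted(
        range(len(annotations)),
        key=lambda i: (
            -annotations[i].length,
            annotations[i].start,
            _SOURCE_RANK[annotations[i].source],
            i,
        ),
    )
    kept: list[DomainInterval] = []
    flagged: list[DomainInterval] = []
    kept_by_seq: dict[str, list[DomainInterval]] = {}
    for i in order:
        iv = annotations[i]
        if any(iv.overlaps(k) for k in kept_by_seq.get(iv.seq_id, ())):
            flagged.append(iv)
        else:
            kept.append(iv)
            kept_by_seq.setdefault(iv.seq_id, []).append(iv)
    return kept, flagged


def extend_annotations(
    curated: Sequence[DomainInterval],
    hits: Iterable,
    seq_lengths: dict[str, int],
    evalue_max: float = 1e-4,
    kind: str = "RRM",
) -> list[DomainInterval]:
    """Augment curated annotations with homology-derived intervals.

    Each similarity hit with ``evalue <= evalue_max`` contributes a
    homology-source interval spanning its query coordinates.  Hits must
    reference known sequences; coordinates are clipped to the sequence.
    Returns curated + new intervals, ready for :func:`reduce_overlaps`.
    """
    new: list[DomainInterval] = []
    for h in hits:
        if h.query_id not in seq_lengths:
            raise KeyError(f"hit references unknown sequence id {h.query_id!r}")
        if h.evalue > evalue_max:
            continue
        if h.qstart is None or h.qend is None:
            raise ValueError(f"hit {h.query_id}->{h.subject_id} lacks query coordinates")
        end = min(h.qend, seq_lengths[h.query_id])
        new.append(
            DomainInterval(h.query_id, h.qstart, end, kind=kind, source="homology")
        )
    return list(curated) + new


def fragment_decompose(
    seq_length: int,
    kept: Sequence[DomainInterval],
    buffer: int = DEFAULT_BUFFER,
) -> list[Fragment]:
    """Split a sequence into buffered inter-domain fragments.

    One fragment precedes the first kept domain (n_terminal), one lies
    between each adjacent domain pair (internal), one follows the last
    domain (c_terminal).  Raw fragment bounds are the inter-domain gap,
    extended by ``buffer`` residues into the flanking domain(s) and
    clipped to [1, seq_length]; a zero-length raw gap between adjacent
    domains still yields a 2*buffer fragment straddling the junction.
    With no domains the whole sequence is a single n_terminal fragment.
    Fragments emptied by clipping are dropped.
    """
    if seq_length < 1:
        raise ValueError("seq_length must be >= 1")
    doms = sorted(kept, key=lambda d: d.start)
    for a, b in zip(doms, doms[1:]):
        if a.end >= b.start:
            raise ValueError("kept domains must be non-overlapping")
    if doms and doms[-1].end > seq_length:
        raise ValueError("domain extends beyond sequence length")
    seq_id = doms[0].seq_id if doms else ""
    if not doms:
        return [Fragment(seq_id, 1, seq_length, "n_terminal")]

    frags: list[Fragment] = []

    def _add(start: int, end: int, cls: str) -> None:
        start, end = max(1, start), min(seq_length, end)
        if start <= end:
            frags.append(Fragment(seq_id, start, end, cls))

    _add(1, doms[0].start - 1 + buffer, "n_terminal")
    for a, b in zip(doms, doms[1:]):
        _add(a.end + 1 - buffer, b.start - 1 + buffer, "internal")
    _add(doms[-1].end + 1 - buffer, seq_length, "c_terminal")
    return frags


def count_prion_fragments(
    scored: Sequence[tuple[Fragment, PrionScore | None]],
) -> tuple[int, int, int]:
    """Count prion-like fragments at both thresholds.

    ``scored`` pairs each fragment with its parse score (None, or a
    sentinel score, for fragments shorter than the core length).
    Returns (count at LLR > 0.0, count at LLR >= 15.0, internal-only
    count at LLR > 0.0).
    """
    n0 = n15 = internal0 = 0
    for frag, score in scored:
        if score is None or score.best_interval is None:
            continue
        if score.best_llr > 0.0:
            n0 += 1
            if frag.position_class == "internal":
                internal0 += 1
        if score.best_llr >= 15.0:
            n15 += 1
    return n0, n15, internal0
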