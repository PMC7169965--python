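"""Orthology and paralogy filters over tabular similarity data.

The similarity search itself happens outside the package (any engine
producing BLAST outfmt-6-style tables works); these functions implement
the decision logic: reciprocal-best-hit (RBH) pairing, cross-referencing
against curated ortholog sets and reference proteomes, and the
comparative paralog sieve that labels a proteome sequence a candidate
Pub1/Nam8 paralog when its best qualifying hit (e-value <= 1e-4,
query coverage > 0.5) prefers the Pub1/Tia1 or Nam8/Ngr1 reference sets
over the Pab1 set.  "Preference" is operationalised as the best hit by
bitscore (database-size independent), with e-value as tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

DEFAULT_EVALUE_MAX = 1e-4
DEFAULT_MIN_COVERAGE = 0.5


@dataclass(frozen=True)
class HitRecord:
    """One similarity hit; coverage is the aligned fraction of the query."""

    query_id: str
    subject_id: str
    evalue: float
    query_coverage: float
    bitscore: float
    qstart: Optional[int] = None   # 1-based query coords, for domain extension
    qend: Optional[int] = None
    pident: float = 0.0

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative e-value for {self.query_id}->{self.subject_id}")
        if not 0.0 <= self.query_coverage <= 1.0:
            raise ValueError(
                f"query_coverage outside [0,1] for {self.query_id}->{self.subject_id}: "
                f"{self.query_coverage}"
            )


@dataclass(frozen=True)
class ReferenceSets:
    """The three curated reference id sets; pairwise disjoint."""

    pub1_ids: frozenset[str]
    nam8_ids: frozenset[str]
    pab1_ids: frozenset[str]

    def __post_init__(self) -> None:
        sets = [self.pub1_ids, self.nam8_ids, self.pab1_ids]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError("reference id sets must be pairwise disjoint")

    @property
    def all_ids(self) -> frozenset[str]:
        return self.pub1_ids | self.nam8_ids | self.pab1_ids

    @property
    def target_ids(self) -> frozenset[str]:
        """The sets whose preference marks a candidate paralog."""
        return self.pub1_ids | self.nam8_ids


def _unique_best(hits: Iterable[HitRecord]) -> dict[str, str]:
    """query -> unique best subject by bitscore; ties disqualify the query."""
    best: dict[str, tuple[float, str, bool]] = {}  # (bitscore, subject, tied)
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or h.bitscore > cur[0]:
            best[h.query_id] = (h.bitscore, h.subject_id, False)
        elif h.bitscore == cur[0] and h.subject_id != cur[1]:
            best[h.query_id] = (cur[0], cur[1], True)
    return {q: s for q, (_, s, tied) in best.items() if not tied}


def rbh_pairs(
    hits_ab: Iterable[HitRecord], hits_ba: Iterable[HitRecord]
) -> set[tuple[str, str]]:
    """Reciprocal best hits between two proteomes.

    (a, b) is returned iff b is a's unique best subject in ``hits_ab``
    and a is b's unique best subject in ``hits_ba``; equal-bitscore best
    -hit ties disqualify the query on that side.
    """
    best_ab = _unique_best(hits_ab)
    best_ba = _unique_best(hits_ba)
    return {(a, b) for a, b in best_ab.items() if best_ba.get(b) == a}


def cross_reference(
    orthodb_ids: Iterable[str],
    rbh_ids: Iterable[str],
    reference_proteome_ids: Iterable[str],
) -> pd.DataFrame:
    """Flag curated ortholog ids against RBH status and reference proteomes.

    Ids absent from the reference proteomes are excluded entirely; the
    remaining ids carry (in_reference_proteome, is_rbh_ortholog) flags.
    """
    rbh = set(rbh_ids)
    proteome = set(reference_proteome_ids)
    rows = [
        {"id": i, "in_reference_proteome": True, "is_rbh_ortholog": i in rbh}
        for i in orthodb_ids
        if i in proteome
    ]
    return pd.DataFrame(rows, columns=["id", "in_reference_proteome", "is_rbh_ortholog"])


def paralog_sieve(
    self_hits: Iterable[HitRecord],
    refs: ReferenceSets,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> set[str]:
    """Comparative sieve for candidate Pub1/Tia1 or Nam8/Ngr1 paralogs.

    A proteome sequence is returned iff it has at least one qualifying
    hit (e-value <= ``evalue_max`` and query coverage > ``min_coverage``
    against a reference-set sequence) and its best qualifying hit — by
    bitscore, e-value as tie-break, residual ties excluded — is to the
    Pub1/Tia1 or Nam8/Ngr1 sets rather than Pab1.  Sequences already in
    any reference set are never returned.
    """
    by_query: dict[str, list[HitRecord]] = {}
    for h in self_hits:
        if h.evalue <= evalue_max and h.query_coverage > min_coverage:
            if h.subject_id in refs.all_ids:
                by_query.setdefault(h.query_id, []).append(h)

    out: set[str] = set()
    for q, hits in by_query.items():
        if q in refs.all_ids:
            continue
        hits.sort(key=lambda h: (-h.bitscore, h.evalue))
        top = hits[0]
        tied = [
            h for h in hits
            if h.bitscore == top.bitscore and h.evalue == top.evalue
            and h.subject_id != top.subject_id
        ]
        if tied:
            continue
        if top.subject_id in refs.target_ids:
            out.add(q)
    return out
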