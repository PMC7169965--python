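"""End-to-end per-protein annotation.

Combines the stages into one pass over a sequence set: consolidate
domain annotations, decompose each protein into buffered inter-domain
fragments, score the whole protein and every fragment for prion-like
composition, scan for Q/N compositional bias, and emit one annotation
row per protein (the schema behind the family-level summaries).
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .bias import best_of_qn
from .domains import (
    DEFAULT_BUFFER,
    DomainInterval,
    count_prion_fragments,
    fragment_decompose,
    reduce_overlaps,
)
from .io import ProteinRecord
from .params import ScoreParams
from .prion import map_parse_llr

ANNOTATION_COLUMNS = [
    "seq_id", "species", "family", "clade", "best_llr",
    "n_prion_domains_at_0", "n_prion_domains_at_15", "n_internal_prion_at_0",
    "n_rrm", "pct_disorder_a", "pct_disorder_b", "log10_flps_p",
]


def annotate_proteins(
    records: Sequence[ProteinRecord],
    annotations: Sequence[DomainInterval],
    params: Optional[ScoreParams] = None,
    buffer: int = DEFAULT_BUFFER,
    clade_map: Optional[dict[str, str]] = None,
    disorder: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Build the per-protein annotation table.

    ``annotations`` are the (already merged, possibly homology-extended)
    domain intervals; they are overlap-reduced here.  ``disorder`` may
    supply precomputed per-protein disorder percentages (columns seq_id,
    pct_disorder_a, pct_disorder_b); absent values are NaN.
    """
    params = params or ScoreParams.default()
    kept, _ = reduce_overlaps(annotations)
    kept_by_seq: dict[str, list[DomainInterval]] = {}
    for d in kept:
        kept_by_seq.setdefault(d.seq_id, []).append(d)

    dis = {}
    if disorder is not None:
        for r in disorder.itertuples(index=False):
            dis[r.seq_id] = (
                getattr(r, "pct_disorder_a", float("nan")),
                getattr(r, "pct_disorder_b", float("nan")),
            )

    rows = []
    for rec in records:
        doms = sorted(kept_by_seq.get(rec.id, []), key=lambda d: d.start)
        frags = fragment_decompose(rec.length, doms, buffer=buffer) if doms else \
            fragment_decompose(rec.length, [], buffer=buffer)
        scored = [
            (f, map_parse_llr(rec.sequence[f.start - 1:f.end], params,
                              seq_id=f"{rec.id}:{f.start}-{f.end}"))
            for f in frags
        ]
        n0, n15, internal0 = count_prion_fragments(scored)
        whole = map_parse_llr(rec.sequence, params, seq_id=rec.id)
        bias = best_of_qn(rec.sequence, seq_id=rec.id)
        da, db = dis.get(rec.id, (float("nan"), float("nan")))
        rows.append({
            "seq_id": rec.id,
            "species": rec.species,
            "family": rec.family,
            "clade": (clade_map or {}).get(rec.id, ""),
            "best_llr": whole.best_llr,
            "n_prion_domains_at_0": n0,
            "n_prion_domains_at_15": n15,
            "n_internal_prion_at_0": internal0,
            "n_rrm": sum(1 for d in doms if d.kind == "RRM"),
            "pct_disorder_a": da,
            "pct_disorder_b": db,
            "log10_flps_p": bias.log10_p,
        })
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
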