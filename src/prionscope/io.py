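"""File formats: FASTA records, outfmt-6 hit tables, interval/score TSVs.

All tabular coordinates are 1-based inclusive.  FASTA headers carry the
species and family labels as ``key=value`` tokens after the identifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .domains import DomainInterval, Fragment
from .homology import HitRecord

#: standard BLAST tabular (outfmt 6) column names
OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str
    species: str = ""
    family: str = "other"   # "Pub1/Tia1" | "Nam8/Ngr1" | "other"

    @property
    def length(self) -> int:
        return len(self.sequence)


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA wrapped at 60 columns."""
    seqs = [
        SeqRecord(
            Seq(r.sequence),
            id=r.id,
            description=f"species={r.species} family={r.family}",
        )
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = dict(
            t.split("=", 1) for t in rec.description.split()[1:] if "=" in t
        )
        out.append(
            ProteinRecord(
                id=rec.id,
                sequence=str(rec.seq),
                species=tokens.get("species", ""),
                family=tokens.get("family", "other"),
            )
        )
    return out


def write_hits_outfmt6(hits: Sequence[HitRecord],
                       query_lengths: dict[str, int],
                       path: str | Path) -> None:
    """Write hits as a BLAST outfmt-6-style TSV (no header, 12 columns)."""
    rows = []
    for h in hits:
        qlen = query_lengths[h.query_id]
        span = max(1, round(h.query_coverage * qlen))
        qstart = h.qstart if h.qstart is not None else 1
        qend = h.qend if h.qend is not None else qstart + span - 1
        rows.append([
            h.query_id, h.subject_id, round(h.pident, 2), qend - qstart + 1,
            0, 0, qstart, qend, 1, qend - qstart + 1, h.evalue, h.bitscore,
        ])
    pd.DataFrame(rows, columns=OUTFMT6_COLUMNS).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_hits_outfmt6(path: str | Path,
                      query_lengths: dict[str, int]) -> list[HitRecord]:
    """Read an outfmt-6 table; coverage = aligned query span / query length."""
    df = pd.read_csv(path, sep="\t", header=None, names=OUTFMT6_COLUMNS)
    hits = []
    for row in df.itertuples(index=False):
        qlen = query_lengths[row.qseqid]
        coverage = min(1.0, (row.qend - row.qstart + 1) / qlen)
        hits.append(
            HitRecord(
                query_id=str(row.qseqid),
                subject_id=str(row.sseqid),
                evalue=float(row.evalue),
                query_coverage=coverage,
                bitscore=float(row.bitscore),
                qstart=int(row.qstart),
                qend=int(row.qend),
                pident=float(row.pident),
            )
        )
    return hits


def write_domains_tsv(intervals: Sequence[DomainInterval], path: str | Path) -> None:
    pd.DataFrame(
        [(d.seq_id, d.start, d.end, d.kind, d.source) for d in intervals],
        columns=["seq_id", "start", "end", "kind", "source"],
    ).to_csv(path, sep="\t", index=False)


def read_domains_tsv(path: str | Path) -> list[DomainInterval]:
    df = pd.read_csv(path, sep="\t")
    return [
        DomainInterval(str(r.seq_id), int(r.start), int(r.end),
                       kind=str(r.kind), source=str(r.source))
        for r in df.itertuples(index=False)
    ]


def write_fragments_tsv(fragments: Sequence[Fragment], path: str | Path) -> None:
    pd.DataFrame(
        [(f.seq_id, f.start, f.end, f.position_class) for f in fragments],
        columns=["seq_id", "start", "end", "position_class"],
    ).to_csv(path, sep="\t", index=False)
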