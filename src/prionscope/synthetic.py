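"""Synthetic ortholog families with known ground truth.

The generator emulates the structure of curated eukaryotic ortholog
families of RRM-containing RNA-binding proteins: each sequence carries
1–4 conserved ~80-residue RRM-like domains separated by i.i.d. linkers,
plus zero or more planted N/Q-enriched tracts of tunable length and
enrichment placed in terminal or inter-domain linkers.  Fabricated
self-proteome similarity tables with controlled e-values and coverage
exercise the orthology/paralogy filters.  All randomness flows from the
single integer seed in :class:`FamilySpec`; identical specs produce
byte-identical output.

No attempt is made to simulate phylogenetic sequence evolution: domains
are mutated copies of a fixed consensus, linkers are i.i.d. background
draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .homology import HitRecord, ReferenceSets
from .io import ProteinRecord
from .params import AA20, ScoreParams

#: fixed 80-residue RRM-like consensus: two beta-strand-like RNP motifs
#: (aromatic/hydrophobic) embedded in an alpha-beta scaffold.  Domains of
#: other lengths tile / truncate this string.
RRM_CONSENSUS = (
    "KLFVGGLSFDTTEESLRNYFEQWGKLTDCVVMRDPNTKRSRGFGFVTYATVEEVDAAMNARPHKVDGRVVEPKRAVSRED"
)
assert len(RRM_CONSENSUS) == 80

SCENARIOS = ("rbh", "paralog", "domain_extension")


class InfeasibleSpecError(ValueError):
    """The requested features cannot fit in the implied sequence layout."""


@dataclass
class FamilySpec:
    """Study conditions for one synthetic ortholog family.

    Defaults mirror the families under study: ~100 orthologs, three
    RRM domains of 80 residues, one N/Q tract of 60 residues at 70%
    Q+N content, linkers of 40–90 residues, 10% per-site domain
    divergence.
    """

    n_sequences: int = 100
    n_domains_range: tuple[int, int] = (3, 3)
    domain_length: int = 80
    linker_length_range: tuple[int, int] = (40, 90)
    prion_tracts_per_seq: tuple[int, int] = (1, 1)
    tract_length: int = 60
    tract_qn_fraction: float = 0.7
    tract_placement: str = "mixed"   # "terminal" | "internal" | "mixed"
    background_freqs: Optional[dict[str, float]] = None
    mutation_rate: float = 0.1
    seed: int = 0
    family_name: str = "Pub1/Tia1"
    id_prefix: str = "SYN"

    def __post_init__(self) -> None:
        if self.background_freqs is None:
            self.background_freqs = dict(ScoreParams.default().f_background)
        total = sum(self.background_freqs.get(aa, 0.0) for aa in AA20)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"background frequencies sum to {total}, not 1")
        if not 0.0 <= self.tract_qn_fraction <= 1.0:
            raise ValueError("tract_qn_fraction must lie in [0, 1]")
        if not 0.0 <= self.mutation_rate < 1.0:
            raise ValueError("mutation_rate must lie in [0, 1)")
        if self.tract_placement not in ("terminal", "internal", "mixed"):
            raise ValueError(f"unknown tract_placement {self.tract_placement!r}")
        bg_qn = self.background_freqs.get("Q", 0) + self.background_freqs.get("N", 0)
        if self.prion_tracts_per_seq[1] > 0 and self.tract_qn_fraction < bg_qn:
            raise ValueError(
                "tract_qn_fraction must be >= background Q+N frequency "
                f"({bg_qn:.4f}) when tracts are planted"
            )


@dataclass
class SyntheticTruth:
    """Planted feature intervals, 1-based inclusive, per sequence."""

    features: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["seq_id", "feature_type", "start", "end", "cls"]
        )
    )

    def of(self, seq_id: str, feature_type: str | None = None) -> pd.DataFrame:
        df = self.features[self.features.seq_id == seq_id]
        if feature_type is not None:
            df = df[df.feature_type == feature_type]
        return df

    def domains(self, seq_id: str) -> list[tuple[int, int]]:
        df = self.of(seq_id, "domain")
        return [(int(r.start), int(r.end)) for r in df.itertuples(index=False)]

    def tracts(self, seq_id: str) -> list[tuple[int, int, str]]:
        df = self.of(seq_id, "tract")
        return [(int(r.start), int(r.end), str(r.cls))
                for r in df.itertuples(index=False)]

    def to_tsv(self, path) -> None:
        self.features.to_csv(path, sep="\t", index=False)


def _draw_background(rng: np.random.Generator, n: int,
                     freqs: dict[str, float]) -> str:
    probs = np.array([freqs[aa] for aa in AA20])
    probs = probs / probs.sum()
    return "".join(rng.choice(list(AA20), size=n, p=probs))


def _make_domain(rng: np.random.Generator, length: int, mutation_rate: float,
                 freqs: dict[str, float]) -> str:
    reps = -(-length // len(RRM_CONSENSUS))
    base = (RRM_CONSENSUS * reps)[:length]
    chars = list(base)
    for i in range(length):
        if rng.random() < mutation_rate:
            chars[i] = _draw_background(rng, 1, freqs)
    return "".join(chars)


def _make_tract(rng: np.random.Generator, length: int, qn_fraction: float,
                freqs: dict[str, float]) -> str:
    chars = []
    for _ in range(length):
        if rng.random() < qn_fraction:
            chars.append("Q" if rng.random() < 0.5 else "N")
        else:
            chars.append(_draw_background(rng, 1, freqs))
    return "".join(chars)


def generate_family(spec: FamilySpec) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """Generate one family of sequences with recorded planted features."""
    rng = np.random.default_rng(spec.seed)
    records: list[ProteinRecord] = []
    rows: list[dict] = []

    for s in range(spec.n_sequences):
        seq_id = f"{spec.id_prefix}{s:04d}"
        lo, hi = spec.n_domains_range
        n_domains = int(rng.integers(lo, hi + 1))
        tlo, thi = spec.prion_tracts_per_seq
        n_tracts = int(rng.integers(tlo, thi + 1))

        n_slots = n_domains + 1  # linker slots: 0 .. n_domains
        if spec.tract_placement == "terminal":
            eligible = sorted({0, n_domains})
        elif spec.tract_placement == "internal":
            eligible = list(range(1, n_domains))
        else:
            eligible = list(range(n_slots))
        if n_tracts > len(eligible):
            raise InfeasibleSpecError(
                f"{n_tracts} tracts requested but only {len(eligible)} eligible "
                f"linker slots with {n_domains} domains and "
                f"placement={spec.tract_placement!r}"
            )
        tract_slots = (
            sorted(rng.choice(eligible, size=n_tracts, replace=False).tolist())
            if n_tracts
            else []
        )

        parts: list[str] = []
        pos = 0  # residues emitted so far

        def _emit(segment: str) -> tuple[int, int]:
            nonlocal pos
            parts.append(segment)
            start = pos + 1
            pos += len(segment)
            return start, pos

        llo, lhi = spec.linker_length_range
        for slot in range(n_slots):
            linker_len = int(rng.integers(llo, lhi + 1)) if lhi >= llo > 0 else 0
            if slot in tract_slots:
                tract = _make_tract(
                    rng, spec.tract_length, spec.tract_qn_fraction,
                    spec.background_freqs,
                )
                if slot == 0:
                    t0, t1 = _emit(tract)
                    _emit(_draw_background(rng, linker_len, spec.background_freqs))
                elif slot == n_domains:
                    _emit(_draw_background(rng, linker_len, spec.background_freqs))
                    t0, t1 = _emit(tract)
                else:
                    half = linker_len // 2
                    _emit(_draw_background(rng, half, spec.background_freqs))
                    t0, t1 = _emit(tract)
                    _emit(_draw_background(rng, linker_len - half,
                                           spec.background_freqs))
                cls = ("n_terminal" if slot == 0
                       else "c_terminal" if slot == n_domains
                       else "internal")
                rows.append({"seq_id": seq_id, "feature_type": "tract",
                             "start": t0, "end": t1, "cls": cls})
            else:
                _emit(_draw_background(rng, linker_len, spec.background_freqs))
            if slot < n_domains:
                dom = _make_domain(rng, spec.domain_length, spec.mutation_rate,
                                   spec.background_freqs)
                d0, d1 = _emit(dom)
                rows.append({"seq_id": seq_id, "feature_type": "domain",
                             "start": d0, "end": d1, "cls": "domain"})

        records.append(
            ProteinRecord(
                id=seq_id,
                sequence="".join(parts),
                species=f"sp{s:04d}",
                family=spec.family_name,
            )
        )

    truth = SyntheticTruth(
        pd.DataFrame(rows, columns=["seq_id", "feature_type", "start", "end", "cls"])
    )
    return records, truth


@dataclass
class HitScenario:
    """Fabricated similarity tables plus the expected downstream answer."""

    tables: dict[str, list[HitRecord]]
    expected: object
    refs: Optional[ReferenceSets] = None


def generate_hit_table(
    records: list[ProteinRecord],
    truth: SyntheticTruth,
    scenario: str,
    seed: int = 0,
) -> HitScenario:
    """Fabricate similarity tables realizing a named filter scenario.

    * ``rbh`` — splits the records into two pseudo-proteomes and plants
      mutual unique best hits pairing them index-wise, plus weaker
      off-target hits; expected = the planted pair set.
    * ``paralog`` — fabricates self-proteome searches where ~40% of the
      records prefer the Pub1/Nam8 reference sets with qualifying
      e-value and coverage, and the rest fail exactly one condition;
      expected = the planted preferrer id set.
    * ``domain_extension`` — emits hits whose query coordinates are the
      planted domain intervals, alternating qualifying (1e-10) and
      non-qualifying (1e-3) e-values; expected = qualifying intervals.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    if not records:
        raise ValueError("records must be non-empty")
    rng = np.random.default_rng(seed)

    if scenario == "rbh":
        half = len(records) // 2
        a, b = records[:half] or records[:1], records[half:] or records[:1]
        n = min(len(a), len(b))
        hits_ab, hits_ba, pairs = [], [], set()
        for i in range(n):
            top = 200.0 + float(rng.random()) * 50.0
            hits_ab.append(HitRecord(a[i].id, b[i].id, 1e-50, 0.95, top))
            hits_ba.append(HitRecord(b[i].id, a[i].id, 1e-50, 0.95, top))
            pairs.add((a[i].id, b[i].id))
            # weaker off-diagonal noise
            j = (i + 1) % n
            if j != i:
                hits_ab.append(HitRecord(a[i].id, b[j].id, 1e-10, 0.6,
                                         top - 50.0 - float(rng.random()) * 20.0))
                hits_ba.append(HitRecord(b[i].id, a[j].id, 1e-10, 0.6,
                                         top - 50.0 - float(rng.random()) * 20.0))
        return HitScenario({"ab": hits_ab, "ba": hits_ba}, pairs)

    if scenario == "paralog":
        refs = ReferenceSets(
            pub1_ids=frozenset({"PUB1_REF_1", "PUB1_REF_2"}),
            nam8_ids=frozenset({"NAM8_REF_1"}),
            pab1_ids=frozenset({"PAB1_REF_1", "PAB1_REF_2"}),
        )
        n = len(records)
        n_planted = max(1, round(0.4 * n))
        planted = {r.id for r in records[:n_planted]}
        targets = sorted(refs.target_ids)
        decoys = sorted(refs.pab1_ids)
        hits: list[HitRecord] = []
        for k, rec in enumerate(records):
            target = targets[k % len(targets)]
            decoy = decoys[k % len(decoys)]
            if rec.id in planted:
                hits.append(HitRecord(rec.id, target,
                                      10.0 ** -float(rng.uniform(6, 30)),
                                      float(rng.uniform(0.55, 0.95)),
                                      150.0 + float(rng.random()) * 20.0))
                hits.append(HitRecord(rec.id, decoy, 1e-6, 0.6,
                                      80.0 + float(rng.random()) * 10.0))
            else:
                mode = k % 4
                if mode == 0:    # best qualifying hit prefers Pab1
                    hits.append(HitRecord(rec.id, decoy, 1e-20, 0.8, 180.0))
                    hits.append(HitRecord(rec.id, target, 1e-10, 0.7, 120.0))
                elif mode == 1:  # e-value fails the 1e-4 cutoff
                    hits.append(HitRecord(rec.id, target, 1e-3, 0.8, 60.0))
                elif mode == 2:  # coverage fails the >0.5 rule
                    hits.append(HitRecord(rec.id, target, 1e-20, 0.3, 90.0))
                # mode 3: no hits at all
        return HitScenario({"self": hits}, planted, refs=refs)

    # domain_extension
    hits = []
    expected: list[tuple[str, int, int]] = []
    k = 0
    for rec in records:
        for (d0, d1) in truth.domains(rec.id):
            qualifying = k % 2 == 0
            ev = 1e-10 if qualifying else 1e-3
            hits.append(HitRecord(rec.id, f"RRM_LIB_{k % 5}", ev,
                                  (d1 - d0 + 1) / rec.length,
                                  100.0, qstart=d0, qend=d1))
            if qualifying:
                expected.append((rec.id, d0, d1))
            k += 1
    return HitScenario({"library": hits}, expected)
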