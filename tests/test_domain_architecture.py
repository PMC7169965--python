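"""Domain consolidation, fragment decomposition, prion-domain counting."""

import numpy as np
import pytest

from prionscope.domains import (
    DomainInterval,
    Fragment,
    count_prion_fragments,
    extend_annotations,
    fragment_decompose,
    reduce_overlaps,
)
from prionscope.homology import HitRecord
from prionscope.prion import PrionScore

from helpers import random_architecture


def D(seq_id, start, end, **kw):
    return DomainInterval(seq_id, start, end, **kw)


class TestReduceOverlaps:
    def test_longest_first_greedy(self):
        anns = [D("s", 1, 100), D("s", 50, 120), D("s", 200, 250)]
        kept, flagged = reduce_overlaps(anns)
        assert {(d.start, d.end) for d in kept} == {(1, 100), (200, 250)}
        assert [(d.start, d.end) for d in flagged] == [(50, 120)]

    def test_single_interval_untouched(self):
        kept, flagged = reduce_overlaps([D("s", 5, 50)])
        assert len(kept) == 1 and not flagged

    def test_identical_intervals_keep_exactly_one(self):
        kept, flagged = reduce_overlaps([D("s", 10, 40), D("s", 10, 40)])
        assert len(kept) == 1 and len(flagged) == 1

    def test_equal_length_prefers_curated(self):
        anns = [
            D("s", 10, 40, source="homology"),
            D("s", 10, 40, source="curated"),
        ]
        kept, _ = reduce_overlaps(anns)
        assert kept[0].source == "curated"

    def test_different_sequences_never_conflict(self):
        kept, flagged = reduce_overlaps([D("a", 1, 50), D("b", 1, 50)])
        assert len(kept) == 2 and not flagged

    def test_input_not_mutated(self):
        anns = [D("s", 1, 100), D("s", 50, 120)]
        snapshot = list(anns)
        reduce_overlaps(anns)
        assert anns == snapshot

    def test_idempotent_and_nonoverlapping(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 12))
            anns = []
            for _k in range(n):
                start = int(rng.integers(1, 300))
                anns.append(D("s", start, start + int(rng.integers(1, 120))))
            kept, flagged = reduce_overlaps(anns)
            for i, a in enumerate(kept):
                for b in kept[i + 1:]:
                    assert not a.overlaps(b)
            for f in flagged:
                assert any(f.overlaps(k) for k in kept)
            kept2, flagged2 = reduce_overlaps(kept)
            assert set(kept2) == set(kept) and not flagged2


class TestExtendAnnotations:
    LENGTHS = {"s": 500}

    def test_empty_hit_table(self):
        assert extend_annotations([], [], self.LENGTHS) == []

    def test_evalue_above_cutoff_excluded(self):
        hit = HitRecord("s", "lib", 1e-3, 0.2, 50.0, qstart=10, qend=90)
        assert extend_annotations([], [hit], self.LENGTHS) == []

    def test_threshold_applied_per_hit(self, rng):
        hits = []
        for i in range(10):
            ev = 1e-10 if i < 6 else 1e-2
            hits.append(HitRecord("s", f"lib{i}", ev, 0.2, 60.0,
                                  qstart=10 * i + 1, qend=10 * i + 80))
        out = extend_annotations([], hits, self.LENGTHS)
        assert len(out) == 6
        assert all(d.source == "homology" for d in out)
        assert [(d.start, min(d.end, 500)) for d in out] == [
            (10 * i + 1, min(10 * i + 80, 500)) for i in range(6)
        ]

    def test_unknown_sequence_raises(self):
        hit = HitRecord("nope", "lib", 1e-10, 0.2, 50.0, qstart=1, qend=50)
        with pytest.raises(KeyError, match="nope"):
            extend_annotations([], [hit], self.LENGTHS)


class TestFragmentDecompose:
    def test_two_domain_layout(self):
        kept = [D("s", 101, 160), D("s", 201, 260)]
        frags = fragment_decompose(300, kept, buffer=10)
        assert [(f.start, f.end, f.position_class) for f in frags] == [
            (1, 110, "n_terminal"),
            (151, 210, "internal"),
            (251, 300, "c_terminal"),
        ]

    def test_no_domains_whole_sequence(self):
        frags = fragment_decompose(150, [])
        assert [(f.start, f.end, f.position_class) for f in frags] == [
            (1, 150, "n_terminal")
        ]

    def test_adjacent_domains_straddle_junction(self):
        frags = fragment_decompose(200, [D("s", 1, 60), D("s", 61, 120)], buffer=10)
        internal = [f for f in frags if f.position_class == "internal"]
        assert [(f.start, f.end) for f in internal] == [(51, 70)]
        assert internal[0].length == 20

    def test_overlapping_kept_domains_rejected(self):
        with pytest.raises(ValueError, match="non-overlapping"):
            fragment_decompose(300, [D("s", 1, 100), D("s", 50, 150)])

    def test_random_architectures_tile_and_count(self, rng):
        """Unbuffered gaps + domains tile [1, L]; one fragment per gap."""
        for _ in range(100):
            L, doms = random_architecture(rng)
            frags = fragment_decompose(L, doms, buffer=10)
            assert len(frags) == len(doms) + 1
            # reconstruct raw gaps independently and check the tiling
            edges = [(d.start, d.end) for d in doms]
            gaps, cursor = [], 1
            for s, e in edges:
                gaps.append((cursor, s - 1))
                cursor = e + 1
            gaps.append((cursor, L))
            covered = np.zeros(L + 1, dtype=int)
            for s, e in edges + [g for g in gaps if g[0] <= g[1]]:
                covered[s:e + 1] += 1
            assert (covered[1:] == 1).all()
            # each fragment equals its raw gap extended by the buffer into
            # flanking domains only (terminal ends are not extended)
            k = len(doms)
            for i, (f, (gs, ge)) in enumerate(zip(frags, gaps)):
                want_start = gs if i == 0 else max(1, gs - 10)
                want_end = ge if i == k else min(L, ge + 10)
                assert (f.start, f.end) == (want_start, want_end)
                assert 1 <= f.start <= f.end <= L


class TestCountPrionFragments:
    def _score(self, llr):
        return PrionScore("f", llr, (1, 60), llr, llr > 0, llr >= 15)

    def _frag(self, cls):
        return Fragment("s", 1, 100, cls)

    def test_all_below_threshold(self):
        scored = [(self._frag("n_terminal"), self._score(-5.0)),
                  (self._frag("internal"), self._score(-1.0))]
        assert count_prion_fragments(scored) == (0, 0, 0)

    def test_single_terminal_domain(self):
        scored = [(self._frag("c_terminal"), self._score(20.0))]
        assert count_prion_fragments(scored) == (1, 1, 0)

    def test_short_fragment_sentinel_ignored(self):
        scored = [(self._frag("internal"), None),
                  (self._frag("n_terminal"), self._score(16.0)),
                  (self._frag("internal"), self._score(3.0))]
        assert count_prion_fragments(scored) == (2, 1, 1)

    def test_count15_never_exceeds_count0(self, rng):
        for _ in range(20):
            scored = [
                (self._frag(rng.choice(["n_terminal", "internal", "c_terminal"])),
                 self._score(float(rng.normal(5, 15))))
                for _ in range(int(rng.integers(1, 8)))
            ]
            n0, n15, _ = count_prion_fragments(scored)
            assert n15 <= n0


class TestEndToEndCounts:
    def test_terminal_plus_internal_tract(self, params):
        """A protein with one N-terminal and one internal planted tract
        counts (2, 2, 1) after fragment decomposition and scoring."""
        from prionscope.synthetic import FamilySpec, generate_family

        spec = FamilySpec(
            n_sequences=1, n_domains_range=(2, 2),
            prion_tracts_per_seq=(2, 2), tract_qn_fraction=0.9,
            tract_placement="mixed", seed=5,
        )
        # seeds walk deterministic layouts; find one with the target classes
        records = truth = None
        for seed in range(30):
            spec.seed = seed
            recs, tr = generate_family(spec)
            classes = {cls for (_s, _e, cls) in tr.tracts(recs[0].id)}
            if classes == {"n_terminal", "internal"} or classes == {"c_terminal", "internal"}:
                records, truth = recs, tr
                break
        assert records is not None
        rec = records[0]
        doms = [D(rec.id, s, e) for (s, e) in truth.domains(rec.id)]
        frags = fragment_decompose(rec.length, doms)
        from prionscope.prion import map_parse_llr

        scored = [
            (f, map_parse_llr(rec.sequence[f.start - 1:f.end], params))
            for f in frags
        ]
        assert count_prion_fragments(scored) == (2, 2, 1)
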