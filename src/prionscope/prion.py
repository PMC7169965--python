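"""Prion-like composition scoring.

Two scores are computed from the same per-residue log-likelihood ratios
(LLRs) of prion-state vs background amino-acid frequencies:

* ``core_window_score`` — the best fixed-length window of exactly ``c``
  residues (sum of raw per-residue LLRs);
* ``map_parse_llr`` — the primary score: the best single contiguous
  prion-state run of length >= ``c`` under a two-state model with
  geometric run-length priors, found by an O(n) prefix-sum parse.  The
  run score is the summed per-residue LLR plus the transition terms
  (a per-residue stay adjustment and a constant open/close cost).

Decision thresholds on the parse score are ``> 0.0`` (strict) and
``>= 15.0`` (inclusive); the higher cutoff corresponds to the weakest
score observed for a known fungal prion-forming domain.

Sequences shorter than ``c`` cannot contain a qualifying core and are
reported with a "no domain" sentinel (``best_llr`` = NaN, both flags
False).  Ambiguity codes (X/B/Z/U) score 0 and never break a run; input
is case-insensitive and ``*`` stop characters are stripped with a
warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .params import AA20, AMBIGUOUS, ScoreParams

_ALPHABET = set(AA20 + AMBIGUOUS)


class AlphabetError(ValueError):
    """A residue outside the accepted amino-acid alphabet."""


@dataclass
class PrionScore:
    """Per-sequence (or per-fragment) prion-like composition score."""

    seq_id: str
    best_llr: float            # NaN when no core of length >= c fits
    best_interval: tuple[int, int] | None  # 1-based inclusive
    core_score: float
    passes_0: bool
    passes_15: bool

    @property
    def has_domain(self) -> bool:
        return self.best_interval is not None


def clean_sequence(sequence: str, seq_id: str = "") -> str:
    """Uppercase, strip ``*``, and validate against the accepted alphabet."""
    seq = sequence.upper()
    if "*" in seq:
        warnings.warn(
            f"sequence {seq_id or '<anonymous>'}: stripping '*' stop characters",
            stacklevel=2,
        )
        seq = seq.replace("*", "")
    for pos, ch in enumerate(seq, start=1):
        if ch not in _ALPHABET:
            raise AlphabetError(
                f"sequence {seq_id or '<anonymous>'}: invalid residue "
                f"{ch!r} at position {pos}"
            )
    return seq


def per_residue_llr(residue: str, params: ScoreParams) -> float:
    """log_base(f_P(aa) / f_B(aa)); 0.0 for ambiguity codes X/B/Z/U."""
    aa = residue.upper()
    if aa not in _ALPHABET:
        raise AlphabetError(f"invalid residue {aa!r} at position 1")
    return params.llr_of(aa)


def _llr_array(seq: str, params: ScoreParams) -> np.ndarray:
    return params._llr_table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def core_window_score(
    sequence: str, params: ScoreParams, seq_id: str = ""
) -> tuple[float | None, tuple[int, int] | None]:
    """Best window of exactly ``core_length`` residues (raw LLR sum).

    Returns ``(None, None)`` for sequences shorter than the core length.
    Ties are broken leftmost.
    """
    seq = clean_sequence(sequence, seq_id)
    c = params.core_length
    if len(seq) < c:
        return None, None
    vals = _llr_array(seq, params)
    prefix = np.concatenate(([0.0], np.cumsum(vals)))
    window_sums = prefix[c:] - prefix[:-c]
    i = int(np.argmax(window_sums))  # argmax is leftmost on ties
    return float(window_sums[i]), (i + 1, i + c)


def map_parse_llr(sequence: str, params: ScoreParams, seq_id: str = "") -> PrionScore:
    """Best single prion-state run of length >= ``core_length``.

    ``best_llr`` is the run's summed per-residue LLR plus the transition
    terms of the two-state model.  Among score-tied runs the leftmost,
    then shortest, is reported.
    """
    seq = clean_sequence(sequence, seq_id)
    c = params.core_length
    n = len(seq)
    core, core_iv = core_window_score(seq, params, seq_id)
    if n == 0 or n < c:
        return PrionScore(seq_id, float("nan"), None, float("nan"), False, False)

    vals = _llr_array(seq, params)
    adj = vals + params.run_adjust()
    K = params.run_constant()
    prefix = np.concatenate(([0.0], np.cumsum(adj)))

    # pass 1: O(n) max of prefix[e+1] - prefix[s] over runs [s, e], e-s+1 >= c
    best = -np.inf
    run_min = np.inf
    for e in range(c - 1, n):
        s_max = e - c + 1
        run_min = min(run_min, prefix[s_max])
        cand = prefix[e + 1] - run_min
        if cand > best:
            best = cand

    # pass 2: leftmost then shortest interval attaining the max exactly
    interval = None
    for s in range(0, n - c + 1):
        scores = prefix[s + c:] - prefix[s]
        hits = np.flatnonzero(scores == best)
        if hits.size:
            e = s + c - 1 + int(hits[0])
            interval = (s + 1, e + 1)
            break
    assert interval is not None

    best_llr = float(best + K)
    return PrionScore(
        seq_id=seq_id,
        best_llr=best_llr,
        best_interval=interval,
        core_score=float(core),
        passes_0=best_llr > 0.0,
        passes_15=best_llr >= 15.0,
    )


def classify_thresholds(score: PrionScore) -> tuple[bool, bool]:
    """(best_llr > 0.0 strict, best_llr >= 15.0 inclusive); sentinel -> (False, False)."""
    if score.best_interval is None or np.isnan(score.best_llr):
        return False, False
    return score.best_llr > 0.0, score.best_llr >= 15.0


def score_records(records, params: ScoreParams) -> list[PrionScore]:
    """Score an iterable of ProteinRecord-like objects (id + sequence)."""
    return [map_parse_llr(r.sequence, params, seq_id=r.id) for r in records]
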