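"""Compositional-bias scanning for Q / N enrichment.

For each protein the scanner finds the subsequence whose residue count
for a target set (``{Q}``, ``{N}`` or pooled ``{Q, N}``) has the lowest
binomial upper-tail probability given an expected per-residue frequency
(0.05 per residue; 0.10 pooled), and reports its log10 P-value.  The
scan is exhaustive over all windows whose length lies within the
configured bounds (default 15–500 residues, clipped to the sequence).
No multiple-testing correction across windows is applied: the raw
minimal P is the quantity of interest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

_LN10 = math.log(10.0)

DEFAULT_WINDOW_BOUNDS = (15, 500)
DEFAULT_P_EXPECT = 0.05


@dataclass
class BiasResult:
    seq_id: str
    residue_set: str          # "Q", "N" or "QN"
    start: int                # 1-based inclusive
    end: int
    count: int                # matching residues in window
    window: int               # window length
    log10_p: float            # log10 binomial upper tail, always <= 0


def binomial_tail_p(x: int, n: int, p: float) -> float:
    """P(X >= x) for X ~ Binomial(n, p), computed in log space."""
    return math.exp(log10_binomial_tail(x, n, p) * _LN10)


def log10_binomial_tail(x: int, n: int, p: float) -> float:
    """log10 P(X >= x); exactly 0.0 at x = 0."""
    if x < 0 or n < 0 or x > n:
        raise ValueError(f"require 0 <= x <= n, got x={x}, n={n}")
    if not 0.0 < p < 1.0:
        raise ValueError(f"require 0 < p < 1, got p={p}")
    if x == 0:
        return 0.0
    return float(binom.logsf(x - 1, n, p)) / _LN10


def scan_lowest_p(
    sequence: str,
    residue_set: str,
    p_expect: float = DEFAULT_P_EXPECT,
    window_bounds: tuple[int, int] = DEFAULT_WINDOW_BOUNDS,
    seq_id: str = "",
) -> BiasResult:
    """Exhaustive lowest-binomial-P window scan for one residue set.

    ``p_expect`` is the expected frequency for the whole set (the caller
    pools per-residue expectations for multi-residue sets).  Ties are
    broken by leftmost start, then shortest window.  Sequences shorter
    than the lower window bound are scanned at their full length.
    """
    seq = sequence.upper().replace("*", "")
    n = len(seq)
    if n == 0:
        raise ValueError("sequence must be non-empty")
    wmin, wmax = window_bounds
    if wmin < 1:
        raise ValueError("window_bounds minimum must be >= 1")
    lo, hi = min(wmin, n), min(wmax, n)

    member = np.isin(np.frombuffer(seq.encode("ascii"), dtype=np.uint8),
                     [ord(ch) for ch in residue_set])
    cs = np.concatenate(([0], np.cumsum(member)))

    best: tuple[float, int, int] | None = None  # (log10_p, start0, length)
    for L in range(lo, hi + 1):
        counts = cs[L:] - cs[:-L]
        with np.errstate(divide="ignore"):
            lp = binom.logsf(counts - 1, L, p_expect) / _LN10
        lp = np.where(counts == 0, 0.0, lp)
        i = int(np.argmin(lp))  # leftmost on ties
        cand = (float(lp[i]), i, L)
        if best is None or cand < best:
            best = cand
    lp_best, i, L = best
    x = int(cs[i + L] - cs[i])
    return BiasResult(seq_id, residue_set, i + 1, i + L, x, L, lp_best)


def best_of_qn(
    sequence: str,
    p_expect: float = DEFAULT_P_EXPECT,
    window_bounds: tuple[int, int] = DEFAULT_WINDOW_BOUNDS,
    seq_id: str = "",
) -> BiasResult:
    """Most biased subsequence over {Q, N, Q+N}.

    The pooled Q+N scan uses twice the per-residue expectation.  Ties
    across residue sets prefer QN, then Q, then N.
    """
    candidates = [
        scan_lowest_p(sequence, "QN", 2 * p_expect, window_bounds, seq_id),
        scan_lowest_p(sequence, "Q", p_expect, window_bounds, seq_id),
        scan_lowest_p(sequence, "N", p_expect, window_bounds, seq_id),
    ]
    best = candidates[0]
    for cand in candidates[1:]:
        if cand.log10_p < best.log10_p:
            best = cand
    return best
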