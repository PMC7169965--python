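"""Independent oracles and table builders shared across the test suite.

Every oracle here recomputes the quantity under test by direct
enumeration or exact arithmetic, independently of the implementation
path it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np

from prionscope.params import AA20, ScoreParams, TransitionParams


def make_params(
    f_p_overrides: dict[str, float] | None = None,
    f_b_overrides: dict[str, float] | None = None,
    core_length: int = 60,
    log_base: float = math.e,
    transition: TransitionParams | None = None,
) -> ScoreParams:
    """Frequency tables with given overrides, remainder spread uniformly."""

    def build(overrides):
        overrides = overrides or {}
        rest = [aa for aa in AA20 if aa not in overrides]
        remaining = 1.0 - sum(overrides.values())
        table = dict(overrides)
        for aa in rest:
            table[aa] = remaining / len(rest)
        return table

    return ScoreParams(
        f_prion=build(f_p_overrides),
        f_background=build(f_b_overrides),
        log_base=log_base,
        core_length=core_length,
        transition=transition or TransitionParams(),
    )


def identity_params(core_length: int = 60) -> ScoreParams:
    """f_P == f_B: every residue scores 0."""
    return make_params({}, {}, core_length=core_length)


def brute_core_window(seq: str, params: ScoreParams):
    """Exhaustive enumeration of all fixed-length windows."""
    c = params.core_length
    if len(seq) < c:
        return None, None
    vals = [params.llr_of(aa) for aa in seq]
    best, iv = -math.inf, None
    for i in range(len(seq) - c + 1):
        s = sum(vals[i:i + c])
        if s > best:
            best, iv = s, (i + 1, i + c)
    return best, iv


def brute_parse_llr(seq: str, params: ScoreParams):
    """Exhaustive enumeration of all runs of length >= core_length.

    Run score = summed per-residue LLR + per-residue stay adjustment
    + constant open/close cost, i.e. the same two-state model scored
    by direct summation instead of the prefix-sum parse.
    """
    c = params.core_length
    n = len(seq)
    if n < c:
        return None
    vals = np.array([params.llr_of(aa) for aa in seq]) + params.run_adjust()
    K = params.run_constant()
    best = -math.inf
    for i in range(n - c + 1):
        cum = np.cumsum(vals[i:])
        cand = float(np.max(cum[c - 1:])) + K
        if cand > best:
            best = cand
    return best


def brute_bias_scan(seq: str, residue_set: str, p: float, bounds=(15, 500)):
    """Exhaustive lowest log10 binomial tail over all (start, length)."""
    from prionscope.bias import log10_binomial_tail

    n = len(seq)
    lo, hi = min(bounds[0], n), min(bounds[1], n)
    member = [1 if ch in residue_set else 0 for ch in seq]
    best = math.inf
    for L in range(lo, hi + 1):
        for i in range(n - L + 1):
            x = sum(member[i:i + L])
            lp = log10_binomial_tail(x, L, p)
            if lp < best:
                best = lp
    return best


def exact_binomial_tail(x: int, n: int, p: Fraction) -> Fraction:
    """P(X >= x) by exact rational summation."""
    total = Fraction(0)
    for k in range(x, n + 1):
        total += math.comb(n, k) * p**k * (1 - p) ** (n - k)
    return total


def random_architecture(rng: np.random.Generator, seq_id: str = "S"):
    """A random sequence length and sorted non-overlapping domain set."""
    from prionscope.domains import DomainInterval

    seq_length = int(rng.integers(100, 1000))
    k = int(rng.integers(0, 5))
    doms, cursor = [], 1
    for _ in range(k):
        gap = int(rng.integers(0, 60))
        length = int(rng.integers(20, 100))
        start = cursor + gap
        end = start + length - 1
        if end > seq_length:
            break
        doms.append(DomainInterval(seq_id, start, end))
        cursor = end + 1
    return seq_length, doms
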