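"""Independent brute-force oracles used to validate the package's
optimised implementations.  Everything here favours obvious correctness
over speed: exact rational arithmetic and O(n*m) scans only.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def brute_force_overlaps(intervals, chrom, start, end):
    """All interval ids overlapping [start, end) on chrom, by linear scan.

    ``intervals`` is an iterable of (chrom, start, end, id) tuples.
    Overlap of half-open intervals: a.start < b.end and b.start < a.end.
    """
    hits = []
    for c, s, e, iid in intervals:
        if c == chrom and s < end and start < e:
            hits.append(iid)
    return sorted(hits)


def exact_fisher_two_sided(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher's exact probability for [[a, b], [c, d]] via
    exhaustive enumeration of the conditional (hypergeometric)
    distribution in exact rational arithmetic.

    Sums P(table) over every table with the same margins whose
    probability is <= P(observed), the standard two-sided definition.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def p_of(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    p_obs = p_of(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    total = Fraction(0)
    for x in range(lo, hi + 1):
        px = p_of(x)
        if px <= p_obs:
            total += px
    return total


def exact_fisher_one_sided_greater(a: int, b: int, c: int, d: int) -> Fraction:
    """One-sided (greater) Fisher probability: P(X >= a) under the
    hypergeometric null, exact rational arithmetic."""
    r1, r2 = a + b, c + d
    c1 = a + c
    denom = comb(r1 + r2, c1)
    hi = min(r1, c1)
    total = Fraction(0)
    for x in range(a, hi + 1):
        total += Fraction(comb(r1, x) * comb(r2, c1 - x), denom)
    return total


def brute_force_equal_count_bins(values, n_bins):
    """Assign sorted values to ``n_bins`` equal-count bins, remainder to
    the lowest bin; returns list of bins, each a sorted list of values."""
    vals = sorted(values)
    n = len(vals)
    base = n // n_bins
    rem = n - base * n_bins
    sizes = [base + (rem if i == 0 else 0) for i in range(n_bins)]
    bins, i = [], 0
    for s in sizes:
        bins.append(vals[i:i + s])
        i += s
    return bins


def brute_force_oriented_distance(strand, tss, tes, pos):
    """Signed distances (to TSS, to TES) in transcription orientation."""
    if strand == "+":
        return pos - tss, pos - tes
    return tss - pos, tes - pos


def brute_force_median_of_mixture(lo, hi, w, n_draw=200_000, seed=0):
    """Monte-Carlo median of the w:(1-w) high:low pool mixture."""
    rng = np.random.default_rng(seed)
    pick_hi = rng.random(n_draw) < w
    out = np.where(pick_hi,
                   rng.choice(hi, n_draw, replace=True),
                   rng.choice(lo, n_draw, replace=True))
    return float(np.median(out))
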