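"""Independent straight-line oracles used by the test suite.

Deliberately naive implementations (loops, dicts, enumeration) kept
separate from the package code paths they validate.
"""

import itertools
import math
from fractions import Fraction


def chi2_upper_quantile_1df(p, tol=1e-12):
    """1-df chi-square upper-tail quantile by bisection on erfc.

    For X ~ chi2(1), P(X > x) = erfc(sqrt(x/2)); independent of scipy.
    """
    if p >= 1.0:
        return 0.0
    lo, hi = 0.0, 1.0
    while math.erfc(math.sqrt(hi / 2.0)) > p:
        hi *= 2.0
    while hi - lo > tol * max(1.0, hi):
        mid = (lo + hi) / 2.0
        if math.erfc(math.sqrt(mid / 2.0)) > p:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def weighting_oracle(n, m, k_n, k_m):
    """Printed weighting rules, re-implemented straight-line with Fractions.

    Returns (w_asm, w_nonasm, branch).
    """
    if n == 0 or m == 0:
        return Fraction(1), Fraction(1), "degenerate_equal"
    r_n = Fraction(k_n, n)
    r_m = Fraction(k_m, m)
    if k_m == 0 and k_n > 0:
        cutoffs = [Fraction(1, 10), Fraction(3, 10), Fraction(1, 2), Fraction(7, 10), Fraction(9, 10)]
        w = 1
        for c in cutoffs:
            if r_n >= c:
                w += 1
        return Fraction(w), Fraction(1), "binned_no_nonasm_informative"
    if r_n > r_m:
        h = 2 / (1 / r_n + 1 / r_m)
        return r_n / h, r_m / h, "harmonic"
    return Fraction(1), Fraction(1), "equal"


def es_oracle(member_ids, all_scores, member_weighted):
    """Running-sum enrichment score, naive loop."""
    order = sorted(all_scores, key=lambda g: (-all_scores[g], g))
    n = len(order)
    n_h = len(member_ids)
    n_r = sum(abs(member_weighted[g]) for g in member_ids)
    if n_r == 0:
        return 0.0
    running = 0.0
    best = -float("inf")
    for g in order:
        if g in member_ids:
            running += abs(member_weighted[g]) / n_r
        else:
            running -= 1.0 / (n - n_h)
        if running > best:
            best = running
    return best


def sum_oracle(member_weighted):
    total = 0.0
    for v in member_weighted.values():
        total += v
    return total


def sumsq_oracle(member_weighted):
    total = 0.0
    for v in member_weighted.values():
        total += v * v
    return total


def empirical_p_oracle(observed, permuted):
    """Add-one permutation p: (1 + #{perm >= obs}) / (1 + B)."""
    r = sum(1 for x in permuted if x >= observed)
    return (1 + r) / (1 + len(permuted))


def empirical_p_bounds(observed, permuted, rel_eps=1e-9):
    """(lower, upper) bounds on the add-one p, treating float near-ties
    as ambiguous.

    Exact permutation ties (identical score multisets) can round
    differently depending on summation order, so any permuted value
    within ``rel_eps`` of the observed one may legitimately count either
    way; everything else is unambiguous.
    """
    b = len(permuted)
    tol = rel_eps * max(1.0, abs(observed))
    strict = sum(1 for x in permuted if x >= observed + tol)
    loose = sum(1 for x in permuted if x >= observed - tol)
    return (1 + strict) / (1 + b), (1 + loose) / (1 + b)


def bh_oracle(pvalues):
    """Textbook BH step-up, naive."""
    m = len(pvalues)
    indexed = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = indexed[rank - 1]
        val = min(prev, pvalues[i] * m / rank, 1.0)
        adj[i] = val
        prev = val
    return adj


def hypergeom_tail_enumeration(universe_size, term_size, query_size, min_overlap):
    """P(overlap >= min_overlap) by enumerating all query draws.

    Universe is 0..universe_size-1 with the term being the first
    term_size elements; feasible for universe_size <= 12.
    """
    term = set(range(term_size))
    total = 0
    hits = 0
    for query in itertools.combinations(range(universe_size), query_size):
        total += 1
        if len(term.intersection(query)) >= min_overlap:
            hits += 1
    return hits / total


def null_min_tail_exact(sorted_pool, n, threshold):
    """Exact P(min of n draws without replacement <= threshold).

    = 1 - C(S - r, n)/C(S, n) where r = #{pool values <= threshold}.
    """
    s = len(sorted_pool)
    r = sum(1 for v in sorted_pool if v <= threshold)
    if s - r < n:
        return 1.0
    return 1.0 - math.comb(s - r, n) / math.comb(s, n)
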