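"""Independent brute-force oracles, deliberately naive.

These recompute quantities by exhaustive enumeration so that the package's
implementations can be checked against something that shares none of their
code paths.
"""

from __future__ import annotations

from itertools import combinations
from math import comb


def exhaustive_local_alignment_score(
    a: str,
    b: str,
    score_pair,
    gap_open: int,
    gap_extend: int,
) -> int:
    """Best local alignment score by enumerating every monotone residue
    matching.

    Every local alignment (under affine gaps, with boundary gaps removed —
    they only subtract) is a non-empty set of matched residue pairs,
    strictly increasing in both sequences; unmatched stretches between
    consecutive pairs are gap runs costing open + length * extend each.
    The score floor is 0 (the empty alignment).
    """
    best = 0
    la, lb = len(a), len(b)
    for k in range(1, min(la, lb) + 1):
        for ia in combinations(range(la), k):
            for ib in combinations(range(lb), k):
                score = 0
                for t in range(k):
                    score += score_pair(a[ia[t]], b[ib[t]])
                    if t > 0:
                        g = ia[t] - ia[t - 1] - 1
                        h = ib[t] - ib[t - 1] - 1
                        if g > 0:
                            score -= gap_open + g * gap_extend
                        if h > 0:
                            score -= gap_open + h * gap_extend
                best = max(best, score)
    return int(best)


def exhaustive_hypergeometric_tail(k: int, M: int, n: int, N: int) -> float:
    """P(X >= k) by enumerating every n-subset of an N-element population
    containing M carriers."""
    population = [1] * M + [0] * (N - M)
    favorable = sum(
        1 for draw in combinations(range(N), n)
        if sum(population[i] for i in draw) >= k
    )
    return favorable / comb(N, n)
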