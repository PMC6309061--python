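"""Independent oracles used by the test suite.

The enumeration oracle computes the hypergeometric upper tail by
exhaustively listing every possible draw of n publications out of m,
counting those containing at least k of the j marked ones — exact
rational arithmetic, no shared code with the log-space implementation.
"""

from collections import Counter
from fractions import Fraction
from itertools import combinations
from math import comb


def tail_by_enumeration(m: int, n: int, j: int, k: int) -> Fraction:
    """Exact P(X ≥ k) by brute-force enumeration of all C(m, n) draws."""
    favorable = sum(
        1
        for draw in combinations(range(m), n)
        if sum(1 for x in draw if x < j) >= k
    )
    return Fraction(favorable, comb(m, n))


def tail_distribution(m: int, n: int, j: int) -> dict[int, Fraction]:
    """{k: P(X ≥ k)} for every k in 0..min(n, j), by one enumeration."""
    counts = Counter(
        sum(1 for x in draw if x < j) for draw in combinations(range(m), n)
    )
    total = comb(m, n)
    tails: dict[int, Fraction] = {}
    acc = 0
    for i in range(min(n, j), -1, -1):
        acc += counts.get(i, 0)
        tails[i] = Fraction(acc, total)
    return tails
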