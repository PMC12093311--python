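"""Independent brute-force oracles used by the statistical tests."""

from fractions import Fraction
from itertools import combinations


def enum_hypergeom_upper(k: int, set_size: int, query_size: int, background: int) -> Fraction:
    """P(X >= k) by exhaustive enumeration of all draws.

    The population is {0..background-1} with the first ``set_size``
    elements marked as successes; every size-``query_size`` draw is
    enumerated and those overlapping the successes in >= k elements are
    counted.  Exact rational arithmetic, independent of any distribution
    library.
    """
    successes = set(range(set_size))
    total = 0
    hits = 0
    for draw in combinations(range(background), query_size):
        total += 1
        if len(successes.intersection(draw)) >= k:
            hits += 1
    return Fraction(hits, total)


def bh_stepup(p_values):
    """Benjamini-Hochberg q-values straight from the textbook definition:
    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values."""
    m = len(p_values)
    indexed = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = indexed[rank - 1]
        running_min = min(running_min, p_values[i] * m / rank)
        q[i] = min(1.0, running_min)
    return q
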