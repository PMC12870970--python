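"""Brute-force partition-agreement oracles, independent of any library.

Chance correction is computed literally: the expected statistic under the
permutation model is the average over all n! relabelings of the items of one
partition. This is exact (and exponentially slow), which is the point — the
fast implementations are checked against it on small n.
"""

from __future__ import annotations

import math
from collections import Counter
from itertools import permutations


def all_partitions(n: int):
    """Every set partition of range(n), as a label list (restricted growth)."""

    def rec(i, labels, k):
        if i == n:
            yield tuple(labels)
            return
        for lab in range(k + 1):
            labels.append(lab)
            yield from rec(i + 1, labels, max(k, lab + 1))
            labels.pop()

    yield from rec(0, [], 0)


def _pair_same(labels):
    counts = Counter(labels)
    return sum(c * (c - 1) // 2 for c in counts.values())


def _pair_both_same(a, b):
    counts = Counter(zip(a, b))
    return sum(c * (c - 1) // 2 for c in counts.values())


def ari_bruteforce(a, b) -> float:
    """ARI with E[index] from exhaustive enumeration of item permutations."""
    n = len(a)
    s = _pair_both_same(a, b)
    sa, sb = _pair_same(a), _pair_same(b)
    exp = sum(_pair_both_same(a, [b[p] for p in perm]) for perm in permutations(range(n)))
    exp /= math.factorial(n)
    max_s = 0.5 * (sa + sb)
    denom = max_s - exp
    if abs(denom) < 1e-12:
        return 1.0
    return (s - exp) / denom


def _entropy(labels):
    n = len(labels)
    return -sum((c / n) * math.log(c / n) for c in Counter(labels).values())


def _mutual_information(a, b):
    n = len(a)
    joint = Counter(zip(a, b))
    ca, cb = Counter(a), Counter(b)
    mi = 0.0
    for (la, lb), c in joint.items():
        mi += (c / n) * math.log(n * c / (ca[la] * cb[lb]))
    return mi


def ami_bruteforce(a, b) -> float:
    """AMI (max normalization) with E[MI] from exhaustive permutations."""
    n = len(a)
    mi = _mutual_information(a, b)
    exp = sum(
        _mutual_information(a, [b[p] for p in perm]) for perm in permutations(range(n))
    ) / math.factorial(n)
    h_max = max(_entropy(a), _entropy(b))
    denom = h_max - exp
    if abs(denom) < 1e-12:
        return 1.0
    return (mi - exp) / denom
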