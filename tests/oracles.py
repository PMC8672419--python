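"""Independent brute-force oracles used only by the test suite.

Everything here is written with plain Python loops, itertools and exact
``fractions.Fraction`` arithmetic so it shares no code path with the
package's vectorised numpy implementations.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


def jt_stat_plain(groups: list[list[float]]) -> Fraction:
    """JT statistic via explicit pair loops (half-weight ties)."""
    j = Fraction(0)
    for i in range(len(groups)):
        for k in range(i + 1, len(groups)):
            for x in groups[i]:
                for y in groups[k]:
                    if x < y:
                        j += 1
                    elif x == y:
                        j += Fraction(1, 2)
    return j


def jt_enumerate(values: list[float], sizes: list[int]):
    """Full enumeration of the permutation null of J.

    Yields J for every distinct assignment of the observed values (as a
    multiset of positions) to groups of the given sizes.
    """
    n = len(values)
    assert sum(sizes) == n

    def assignments(avail: tuple[int, ...], remaining: list[int]):
        if not remaining:
            yield []
            return
        for combo in itertools.combinations(avail, remaining[0]):
            rest = tuple(i for i in avail if i not in combo)
            for tail in assignments(rest, remaining[1:]):
                yield [combo] + tail

    out = []
    for assign in assignments(tuple(range(n)), list(sizes)):
        groups = [[values[i] for i in part] for part in assign]
        out.append(jt_stat_plain(groups))
    return out


def jt_brute_force(values: list[float], sizes: list[int]) -> dict:
    """Exact p-values and null moments of J by full enumeration."""
    groups, start = [], 0
    for s in sizes:
        groups.append(list(values[start : start + s]))
        start += s
    j_obs = jt_stat_plain(groups)
    dist = jt_enumerate(values, sizes)
    total = len(dist)
    mean = sum(dist, Fraction(0)) / total
    var = sum((d - mean) ** 2 for d in dist) / total
    p_inc = Fraction(sum(1 for d in dist if d >= j_obs), total)
    p_dec = Fraction(sum(1 for d in dist if d <= j_obs), total)
    return {
        "J": j_obs,
        "mean": mean,
        "var": var,
        "p_increasing": p_inc,
        "p_decreasing": p_dec,
        "n_partitions": total,
    }


def t2_survival(t: float) -> float:
    """Closed-form survival function of Student's t with 2 df."""
    return 0.5 * (1.0 - t / math.sqrt(t * t + 2.0))


def hypergeom_upper_tail(k: int, m: int, n: int, big_n: int) -> Fraction:
    """Exact P(X >= k) via the combinatorial sum with Fractions."""
    total = math.comb(big_n, n)
    s = 0
    for j in range(k, min(m, n) + 1):
        s += math.comb(m, j) * math.comb(big_n - m, n - j)
    return Fraction(s, total)


def bh_adjust(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up, computed by hand."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running_min = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        candidate = pvals[i] * m / rank_from_end
        running_min = min(running_min, candidate)
        adj[i] = running_min
    return adj
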