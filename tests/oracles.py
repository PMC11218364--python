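"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by direct enumeration or by the defining
formula, independently of the package's implementation path.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Set, Tuple


def entropy_oracle(weights: Iterable[float]) -> float:
    """-sum p ln p by direct evaluation of the defining formula."""
    w = [float(x) for x in weights]
    total = sum(w)
    return -sum((x / total) * math.log(x / total) for x in w if x > 0)


def bray_curtis_oracle(x: Iterable[float], y: Iterable[float]) -> float:
    """1 - 2 sum(min) / (sum x + sum y) by direct evaluation."""
    xs, ys = list(x), list(y)
    num = sum(min(a, b) for a, b in zip(xs, ys))
    return 1.0 - 2.0 * num / (sum(xs) + sum(ys))


def enumerate_global_alignments(
    a: str, b: str
) -> Set[Tuple[int, int, int]]:
    """All (score, matches, columns) over every global alignment of a, b.

    Scoring: match +1, mismatch 0, each gap column -1.  'N' never matches.
    Exponential enumeration; use only on tiny sequences.
    """
    results: Set[Tuple[int, int, int]] = set()

    def recurse(i: int, j: int, score: int, matches: int, columns: int) -> None:
        if i == len(a) and j == len(b):
            results.add((score, matches, columns))
            return
        if i < len(a) and j < len(b):
            is_match = a[i] == b[j] and a[i] in "ACGT"
            recurse(
                i + 1, j + 1,
                score + (1 if is_match else 0),
                matches + (1 if is_match else 0),
                columns + 1,
            )
        if i < len(a):
            recurse(i + 1, j, score - 1, matches, columns + 1)
        if j < len(b):
            recurse(i, j + 1, score - 1, matches, columns + 1)

    recurse(0, 0, 0, 0, 0)
    return results


def optimal_alignment_identities(a: str, b: str) -> Set[float]:
    """Percent identities attainable by maximum-score global alignments."""
    outcomes = enumerate_global_alignments(a, b)
    best = max(s for s, _, _ in outcomes)
    return {
        100.0 * m / c for s, m, c in outcomes if s == best and c > 0
    }


def mannwhitney_exact_oracle(a, b) -> float:
    """Two-sided exact Mann-Whitney p by enumerating rank assignments."""
    pooled = sorted(list(a) + list(b))
    # mid-ranks
    ranks = {}
    vals = list(a) + list(b)
    order = sorted(range(len(vals)), key=lambda i: vals[i])
    i = 0
    rank_of = [0.0] * len(vals)
    while i < len(order):
        j = i
        while j < len(order) and vals[order[j]] == vals[order[i]]:
            j += 1
        mid = (i + 1 + j) / 2.0
        for k in range(i, j):
            rank_of[order[k]] = mid
        i = j
    n_a = len(a)
    u_obs = sum(rank_of[:n_a]) - n_a * (n_a + 1) / 2.0
    us = []
    for combo in itertools.combinations(range(len(vals)), n_a):
        u = sum(rank_of[k] for k in combo) - n_a * (n_a + 1) / 2.0
        us.append(u)
    p_low = sum(u <= u_obs + 1e-12 for u in us) / len(us)
    p_high = sum(u >= u_obs - 1e-12 for u in us) / len(us)
    return min(1.0, 2.0 * min(p_low, p_high))


def faith_pd_oracle(present, parent_of, length_of, root) -> float:
    """Sum of branch lengths on the union of root-to-leaf paths."""
    edges = set()
    for leaf in present:
        node = leaf
        while node is not None:
            edges.add(node)
            node = parent_of.get(node)
    return sum(length_of.get(e, 0.0) for e in edges)
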