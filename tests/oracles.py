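"""Independent brute-force oracles used only by the test suite.

Everything here is computed from first principles (integer arithmetic,
exhaustive enumeration, all-pairs comparison) without calling the package's
own statistical routines or scipy, so the oracles stay independent of the
code paths they check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric tail summation.

    Conditions on the margins and sums the probabilities of all tables at
    most as probable as the observed one. Table probabilities share the
    denominator C(N, a+c), so the comparison is exact integer arithmetic.
    """
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {x: comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)}
    obs = weights[a]
    num = sum(w for w in weights.values() if w <= obs)
    return float(Fraction(num, comb(r1 + r2, c1)))


def binom_two_sided_oracle(k: int, n: int, s: int, t: int) -> float:
    """Two-sided exact binomial p for k successes in n trials, p = s/t.

    Point masses are carried as exact integers N_j = C(n,j) s^j (t-s)^(n-j)
    (common denominator t^n) via an integer recurrence, so the tie rule
    "pmf(j) <= pmf(k)" is decided without rounding.
    """
    if not 0 < s < t:
        raise ValueError("s/t must lie strictly between 0 and 1")
    weights = [0] * (n + 1)
    w = (t - s) ** n  # j = 0
    weights[0] = w
    for j in range(n):
        w = (w * (n - j) * s) // ((j + 1) * (t - s))
        weights[j + 1] = w
    obs = weights[k]
    num = sum(w for w in weights if w <= obs)
    return float(min(Fraction(num, t ** n), Fraction(1)))


def brute_force_global_groups(items: list[tuple[str, str]],
                              min_unique: int = 2) -> set[tuple[str, frozenset]]:
    """All-pairs single-wildcard clustering of (full_cdr3, trimmed) items.

    Every (sequence, position) mask defines a candidate pattern; membership
    is decided by matching every sequence against every pattern (O(n^2 L)).
    Returns {(pattern, frozenset of member full CDR3s)} for groups with at
    least ``min_unique`` distinct members.
    """
    trimmed_set = sorted({t for _, t in items})
    patterns = set()
    for t in trimmed_set:
        for i in range(len(t)):
            patterns.add(t[:i] + "%" + t[i + 1:])
    out = set()
    for pat in patterns:
        members = set()
        for full, t in items:
            if len(t) != len(pat):
                continue
            if all(p == "%" or p == ch for p, ch in zip(pat, t)):
                members.add(full)
        if len(members) >= min_unique:
            out.add((pat, frozenset(members)))
    return out


def brute_force_edge_weights(motif_nodes: dict[str, set[str]]) -> dict[tuple[str, str], int]:
    """Edge weights of the sharing graph by per-motif pair counting."""
    weights: dict[tuple[str, str], int] = {}
    for nodes in motif_nodes.values():
        ns = sorted(nodes)
        for i in range(len(ns)):
            for j in range(i + 1, len(ns)):
                weights[(ns[i], ns[j])] = weights.get((ns[i], ns[j]), 0) + 1
    return weights
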