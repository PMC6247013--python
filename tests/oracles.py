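"""Independent brute-force oracles used to validate the optimized paths.

Everything here is deliberately naive: plain dictionaries, exact rational
arithmetic where it matters, exhaustive enumeration.  None of it shares
code with the package implementation.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


def brute_counts(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if any(ch not in "ACGT" for ch in w):
            continue
        counts[w] = counts.get(w, 0) + 1
    return counts


def brute_freqs(seq: str) -> dict[str, Fraction]:
    totals = {b: seq.count(b) for b in "ACGT"}
    n = sum(totals.values())
    return {b: Fraction(totals[b], n) for b in "ACGT"}


def brute_d2s(seq_a: str, seq_b: str, k: int) -> tuple[float, float]:
    """Exhaustive-word D2S between two forward-strand sequences.

    Sums over all 4^k words with exact rational backgrounds, then converts
    to float at the very end of each accumulated term.
    """
    ca, cb = brute_counts(seq_a, k), brute_counts(seq_b, k)
    fa, fb = brute_freqs(seq_a), brute_freqs(seq_b)
    na = len(seq_a) - k + 1
    nb = len(seq_b) - k + 1
    raw = 0.0
    A = 0.0
    B = 0.0
    for letters in itertools.product("ACGT", repeat=k):
        w = "".join(letters)
        pa = Fraction(1)
        pb = Fraction(1)
        for ch in w:
            pa *= fa[ch]
            pb *= fb[ch]
        xt = ca.get(w, 0) - na * float(pa)
        yt = cb.get(w, 0) - nb * float(pb)
        denom = math.sqrt(xt * xt + yt * yt)
        if denom == 0:
            continue
        raw += xt * yt / denom
        A += xt * xt / denom
        B += yt * yt / denom
    dis = 0.5 * (1 - raw / math.sqrt(A * B))
    return raw, min(1.0, max(0.0, dis))


def brute_maximal_cliques(nodes: list, edges: set) -> list[frozenset]:
    """All maximal cliques by exhaustive subset enumeration (≤ ~15 nodes)."""
    nodes = list(nodes)
    norm_edges = {frozenset(e) for e in edges}

    def is_clique(subset: tuple) -> bool:
        return all(
            frozenset((u, v)) in norm_edges
            for u, v in itertools.combinations(subset, 2)
        )

    cliques = [
        frozenset(subset)
        for r in range(1, len(nodes) + 1)
        for subset in itertools.combinations(nodes, r)
        if is_clique(subset)
    ]
    return [
        c for c in cliques
        if not any(c < other for other in cliques)
    ]


def brute_clique_stats(nodes: list, edges: set) -> tuple[int, int]:
    """(z, n) by exhaustive enumeration: largest clique size and number of
    maximal cliques on >= 3 nodes."""
    if not nodes:
        return 0, 0
    maximal = brute_maximal_cliques(nodes, edges)
    z = max(len(c) for c in maximal)
    n = sum(1 for c in maximal if len(c) >= 3)
    return z, n


def brute_fisher_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher exact p by direct hypergeometric
    summation with exact integer arithmetic."""
    row1 = a + b
    col1 = a + c
    n = a + b + c + d
    denom = math.comb(n, col1)
    p = Fraction(0)
    for x in range(a, min(row1, col1) + 1):
        if col1 - x > n - row1:
            continue
        p += Fraction(math.comb(row1, x) * math.comb(n - row1, col1 - x), denom)
    return float(p)


def brute_bh(pvalues: list[float]) -> list[float]:
    """Benjamini–Hochberg adjusted p-values, textbook step-up definition."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(1.0, pvalues[i] * m / rank_from_top)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted
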