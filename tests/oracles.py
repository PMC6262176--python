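"""Independent alignment oracles for the test suite.

Two implementations, both independent of the package's aligner:

* ``enum_global_score`` — memoized three-state recursion enumerating all
  alignments of two (short) strings under affine gaps;
* ``enum_local_score`` — brute-force local optimum: the maximum of
  ``enum_global_score`` over every pair of substrings, with 0 (the empty
  alignment) always admissible;
* ``gotoh_local_score`` — plain-Python quadratic-time Gotoh dynamic
  programme, for sequences too long to enumerate.
"""

from __future__ import annotations

import math
from functools import lru_cache

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")
MATRIX = {x: {y: int(_B62[x, y]) for y in _B62.alphabet} for x in _B62.alphabet}

GAP_OPEN = 11
GAP_EXTEND = 1


def enum_global_score(a: str, b: str) -> float:
    """Max score over all global alignments of a vs b (affine gaps)."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0
        best = -math.inf
        if i < len(a) and j < len(b):
            best = max(best, MATRIX[a[i]][b[j]] + rec(i + 1, j + 1, "M"))
        if i < len(a):
            cost = GAP_EXTEND if prev == "D" else GAP_OPEN + GAP_EXTEND
            best = max(best, -cost + rec(i + 1, j, "D"))
        if j < len(b):
            cost = GAP_EXTEND if prev == "I" else GAP_OPEN + GAP_EXTEND
            best = max(best, -cost + rec(i, j + 1, "I"))
        return best

    result = rec(0, 0, "M")
    rec.cache_clear()
    return result


def enum_local_score(q: str, s: str) -> int:
    """Brute-force optimal local score: best global score over all
    substring pairs, floored at 0 (the empty alignment)."""
    best = 0.0
    for i1 in range(len(q)):
        for i2 in range(i1 + 1, len(q) + 1):
            for j1 in range(len(s)):
                for j2 in range(j1 + 1, len(s) + 1):
                    best = max(best, enum_global_score(q[i1:i2], s[j1:j2]))
    return int(best)


def gotoh_local_score(a: str, b: str) -> int:
    """Quadratic-time Smith-Waterman-Gotoh local score, plain Python."""
    neg = -(10 ** 9)
    n = len(b)
    h_prev = [0] * (n + 1)
    f = [neg] * (n + 1)
    best = 0
    for i in range(1, len(a) + 1):
        h_cur = [0] * (n + 1)
        e = neg
        row = MATRIX[a[i - 1]]
        for j in range(1, n + 1):
            e = max(e - GAP_EXTEND, h_cur[j - 1] - GAP_OPEN - GAP_EXTEND)
            f[j] = max(f[j] - GAP_EXTEND, h_prev[j] - GAP_OPEN - GAP_EXTEND)
            h = max(0, h_prev[j - 1] + row[b[j - 1]], e, f[j])
            h_cur[j] = h
            if h > best:
                best = h
        h_prev = h_cur
    return best
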