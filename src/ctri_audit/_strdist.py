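"""Restricted Damerau-Levenshtein (optimal string alignment) distance.

Counts insertions, deletions, substitutions and transpositions of adjacent
characters, each at unit cost. The restricted variant (no substring may be
edited more than once) is what the name-variant matching ladder needs:
person-name typos are overwhelmingly single-character slips and adjacent
swaps, and the restriction is irrelevant at the small cutoffs used here.
"""

from __future__ import annotations


def damerau_levenshtein(a: str, b: str) -> int:
    """Optimal-string-alignment distance between ``a`` and ``b``."""
    if a == b:
        return 0
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    prev2: list[int] = []
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        ca = a[i - 1]
        for j in range(1, lb + 1):
            cost = 0 if ca == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if i > 1 and j > 1 and ca == b[j - 2] and a[i - 2] == b[j - 1]:
                cur[j] = min(cur[j], prev2[j - 2] + 1)
        prev2, prev = prev, cur
    return prev[lb]


def within_edit(a: str, b: str, max_edit: int) -> bool:
    """True iff distance(a, b) <= max_edit, with a cheap length pre-check."""
    if abs(len(a) - len(b)) > max_edit:
        return False
    return damerau_levenshtein(a, b) <= max_edit
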