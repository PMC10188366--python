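"""Independent brute-force oracles used only by tests.

These deliberately share no code with the package: alignment scores are
computed by exhaustively enumerating every global alignment as a sequence of
diagonal / up / left moves and scoring each alignment directly from its
column structure.
"""

from __future__ import annotations

import math

NEG = float("-inf")


def enumerate_best_score(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = 0.0,
    free_start: bool = True,
) -> float:
    """Best global alignment score by exhaustive alignment enumeration.

    A gap run of length L scores gap_open + (L-1)*gap_extend; a run that
    starts at alignment column 0 is free when ``free_start`` is set.  N (or
    any non-ACGT symbol) scores as a mismatch even against itself.
    """
    la, lb = len(a), len(b)
    best = NEG

    def rec(i: int, j: int, col: int, last: str, lead: bool, score: float) -> None:
        nonlocal best
        if i == la and j == lb:
            if score > best:
                best = score
            return
        if i < la and j < lb:
            s = match if (a[i] == b[j] and a[i] in "ACGT") else mismatch
            rec(i + 1, j + 1, col + 1, "D", False, score + s)
        if i < la:  # gap in b
            if last == "U":
                add = 0.0 if lead else gap_extend
                rec(i + 1, j, col + 1, "U", lead, score + add)
            elif col == 0 and free_start:
                rec(i + 1, j, col + 1, "U", True, score)
            else:
                rec(i + 1, j, col + 1, "U", False, score + gap_open)
        if j < lb:  # gap in a
            if last == "L":
                add = 0.0 if lead else gap_extend
                rec(i, j + 1, col + 1, "L", lead, score + add)
            elif col == 0 and free_start:
                rec(i, j + 1, col + 1, "L", True, score)
            else:
                rec(i, j + 1, col + 1, "L", False, score + gap_open)

    rec(0, 0, 0, "", False, 0.0)
    return best


def binom_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), by direct summation."""
    if k <= 0:
        return 1.0
    total = 0.0
    for i in range(k, n + 1):
        total += math.comb(n, i) * p**i * (1 - p) ** (n - i)
    return total


def binom_pmf(k: int, n: int, p: float) -> float:
    return math.comb(n, k) * p**k * (1 - p) ** (n - k)
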