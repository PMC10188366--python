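"""Global sequence alignment for genotyping.

Needleman-Wunsch with affine gaps (Gotoh three-state recursion).  The default
scoring is the one used for target-site genotyping throughout the package:
match +1, mismatch -1, gap open -5, gap extend 0, with leading ("start") gaps
free on both sequences so a read may begin anywhere relative to the reference
cassette without penalty.  Trailing gaps pay the opening penalty unless
``free_end_gaps`` is set.

Traceback tie-breaking is deterministic: diagonal > up (gap in the second
sequence) > left (gap in the first sequence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

_NEG = -1.0e18
_EPS = 1e-9

# base codes: A=0 C=1 G=2 T=3, anything else (incl. N) = 4 and always mismatches
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (A=0,C=1,G=2,T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters for global alignment.

    A gap of length L scores ``gap_open + (L - 1) * gap_extend``.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = 0.0
    free_start_gaps: bool = True
    free_end_gaps: bool = False

    def __post_init__(self) -> None:
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.match < self.mismatch:
            raise ValueError("match score must be >= mismatch score")


@njit(cache=True)
def _gotoh_fill(a, b, match, mismatch, gap_open, gap_extend, free_start):
    n = a.shape[0]
    m = b.shape[0]
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in b: consumes a ("up")
    Y = np.full((n + 1, m + 1), _NEG)  # gap in a: consumes b ("left")
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = 0.0 if free_start else gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = 0.0 if free_start else gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if (ai == b[j - 1] and ai < 4) else mismatch
            p = M[i - 1, j - 1]
            if X[i - 1, j - 1] > p:
                p = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > p:
                p = Y[i - 1, j - 1]
            M[i, j] = p + s
            x = M[i - 1, j] + gap_open
            if X[i - 1, j] + gap_extend > x:
                x = X[i - 1, j] + gap_extend
            if Y[i - 1, j] + gap_open > x:
                x = Y[i - 1, j] + gap_open
            X[i, j] = x
            y = M[i, j - 1] + gap_open
            if X[i, j - 1] + gap_open > y:
                y = X[i, j - 1] + gap_open
            if Y[i, j - 1] + gap_extend > y:
                y = Y[i, j - 1] + gap_extend
            Y[i, j] = y
    return M, X, Y


@njit(cache=True)
def _traceback(M, X, Y, a, b, match, mismatch, gap_open, gap_extend, free_end):
    n = M.shape[0] - 1
    m = M.shape[1] - 1
    # choose end cell; with free ends, trailing unaligned suffixes cost 0
    ei, ej = n, m
    best = M[n, m]
    state = 0  # 0=M (diag), 1=X (up), 2=Y (left)
    if X[n, m] > best + _EPS:
        best, state = X[n, m], 1
    if Y[n, m] > best + _EPS:
        best, state = Y[n, m], 2
    if free_end:
        for i in range(n + 1):
            for st in range(3):
                v = M[i, m] if st == 0 else (X[i, m] if st == 1 else Y[i, m])
                if v > best + _EPS:
                    best, ei, ej, state = v, i, m, st
        for j in range(m + 1):
            for st in range(3):
                v = M[n, j] if st == 0 else (X[n, j] if st == 1 else Y[n, j])
                if v > best + _EPS:
                    best, ei, ej, state = v, n, j, st
    score = best

    max_cols = n + m
    ai = np.empty(max_cols, dtype=np.int32)
    bj = np.empty(max_cols, dtype=np.int32)
    k = max_cols  # fill from the back

    # trailing free gaps
    i, j = n, m
    while i > ei:
        k -= 1
        ai[k] = i - 1
        bj[k] = -1
        i -= 1
    while j > ej:
        k -= 1
        ai[k] = -1
        bj[k] = j - 1
        j -= 1

    while i > 0 or j > 0:
        if state == 0:  # M: emitted column is (i-1, j-1)
            k -= 1
            ai[k] = i - 1
            bj[k] = j - 1
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] < 4) else mismatch
            target = M[i, j] - s
            # predecessor preference: diagonal M > X > Y
            if abs(M[i - 1, j - 1] - target) < _EPS:
                state = 0
            elif abs(X[i - 1, j - 1] - target) < _EPS:
                state = 1
            else:
                state = 2
            i -= 1
            j -= 1
        elif state == 1:  # X: gap in b, consumes a
            k -= 1
            ai[k] = i - 1
            bj[k] = -1
            if j == 0:
                state = 1  # boundary column: keep walking up
            else:
                if abs(M[i - 1, j] + gap_open - X[i, j]) < _EPS:
                    state = 0
                elif abs(X[i - 1, j] + gap_extend - X[i, j]) < _EPS:
                    state = 1
                else:
                    state = 2
            i -= 1
        else:  # Y: gap in a, consumes b
            k -= 1
            ai[k] = -1
            bj[k] = j - 1
            if i == 0:
                state = 2
            else:
                if abs(M[i, j - 1] + gap_open - Y[i, j]) < _EPS:
                    state = 0
                elif abs(X[i, j - 1] + gap_open - Y[i, j]) < _EPS:
                    state = 1
                else:
                    state = 2
            j -= 1

    return score, ai[k:], bj[k:]


def align_codes(
    a: np.ndarray, b: np.ndarray, params: AlignmentParams
) -> tuple[float, np.ndarray, np.ndarray]:
    """Align encoded sequences; return (score, a_indices, b_indices).

    The index arrays have one entry per alignment column; gaps are -1.
    """
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("cannot align an empty sequence")
    M, X, Y = _gotoh_fill(
        a,
        b,
        params.match,
        params.mismatch,
        params.gap_open,
        params.gap_extend,
        params.free_start_gaps,
    )
    return _traceback(
        M,
        X,
        Y,
        a,
        b,
        params.match,
        params.mismatch,
        params.gap_open,
        params.gap_extend,
        params.free_end_gaps,
    )


def needleman_wunsch(
    seq_a: str, seq_b: str, params: AlignmentParams | None = None
) -> tuple[float, str, str]:
    """Globally align two sequences; return (score, aligned_a, aligned_b).

    N (or any non-ACGT symbol) always scores as a mismatch, including against
    another N.
    """
    if params is None:
        params = AlignmentParams()
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    score, ai, bj = align_codes(encode_sequence(seq_a), encode_sequence(seq_b), params)
    aligned_a = "".join(seq_a[i] if i >= 0 else "-" for i in ai)
    aligned_b = "".join(seq_b[j] if j >= 0 else "-" for j in bj)
    return score, aligned_a, aligned_b


def alignment_score(seq_a: str, seq_b: str, params: AlignmentParams | None = None) -> float:
    score, _, _ = needleman_wunsch(seq_a, seq_b, params)
    return score
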