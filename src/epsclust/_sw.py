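"""Numba kernel for local protein alignment (Smith-Waterman / Gotoh).

Affine gap model with the BLAST convention: a gap of length k costs
open + k * extend.  Scores use BLOSUM62; the ambiguity letter X scores 0
against everything.  The kernel performs its own traceback so the caller
receives identity/coverage bookkeeping without materialising alignments.
"""
from __future__ import annotations

import numpy as np
from numba import njit

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_X_CODE = len(AA_ALPHABET) - 1

_CHAR_TO_CODE = np.full(128, _X_CODE, dtype=np.int8)
for _i, _c in enumerate(AA_ALPHABET):
    _CHAR_TO_CODE[ord(_c)] = _i
    _CHAR_TO_CODE[ord(_c.lower())] = _i


def _build_blosum62() -> np.ndarray:
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    n = len(AA_ALPHABET)
    mat = np.zeros((n, n), dtype=np.int32)
    for i, a in enumerate(AA_ALPHABET[:-1]):
        for j, b in enumerate(AA_ALPHABET[:-1]):
            mat[i, j] = int(blosum[a][b])
    # X row/column deliberately 0 (tolerated, neither rewarded nor penalised)
    return mat


BLOSUM62 = _build_blosum62()


def encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CHAR_TO_CODE[arr]


@njit(cache=True)
def _sw_core(a, b, sub, gap_open, gap_extend):  # pragma: no cover - exercised via wrapper
    """Fill DP matrices and trace back the optimal local alignment.

    Returns (score, matches, columns, a_start, a_end, b_start, b_end) where
    the intervals are 0-based half-open over the unaligned sequences.
    Ties on score are broken by the traceback yielding the most alignment
    columns, then by the lowest (i, j) end cell; within a traceback the
    diagonal move is preferred over vertical over horizontal.
    """
    n = a.shape[0]
    m = b.shape[0]
    NEG = np.int32(-(10 ** 9))
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap in b (vertical)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)  # gap in a (horizontal)
    PH = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 stop, 1 diag, 2 E, 3 F
    PE = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1 opened from H
    PF = np.zeros((n + 1, m + 1), dtype=np.uint8)

    open_cost = gap_open + gap_extend
    best = np.int32(0)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            e_open = H[i - 1, j] - open_cost
            e_ext = E[i - 1, j] - gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                PE[i, j] = 1
            else:
                E[i, j] = e_ext
                PE[i, j] = 0
            f_open = H[i, j - 1] - open_cost
            f_ext = F[i, j - 1] - gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                PF[i, j] = 1
            else:
                F[i, j] = f_ext
                PF[i, j] = 0
            diag = H[i - 1, j - 1] + sub[ai, b[j - 1]]
            h = np.int32(0)
            p = np.uint8(0)
            if diag > h:
                h = diag
                p = np.uint8(1)
            if E[i, j] > h:
                h = E[i, j]
                p = np.uint8(2)
            if F[i, j] > h:
                h = F[i, j]
                p = np.uint8(3)
            H[i, j] = h
            PH[i, j] = p
            if h > best:
                best = h

    if best == 0:
        return 0, 0, 0, 0, 0, 0, 0

    best_cols = -1
    best_matches = 0
    best_ai0 = 0
    best_ai1 = 0
    best_bj0 = 0
    best_bj1 = 0
    for i_end in range(1, n + 1):
        for j_end in range(1, m + 1):
            if H[i_end, j_end] != best:
                continue
            # traceback from (i_end, j_end)
            i = i_end
            j = j_end
            cols = 0
            matches = 0
            state = 0  # 0 = H, 1 = E, 2 = F
            while True:
                if state == 0:
                    p = PH[i, j]
                    if p == 0:
                        break
                    if p == 1:
                        cols += 1
                        if a[i - 1] == b[j - 1]:
                            matches += 1
                        i -= 1
                        j -= 1
                    elif p == 2:
                        state = 1
                    else:
                        state = 2
                elif state == 1:
                    cols += 1
                    opened = PE[i, j]
                    i -= 1
                    state = 0 if opened == 1 else 1
                else:
                    cols += 1
                    opened = PF[i, j]
                    j -= 1
                    state = 0 if opened == 1 else 2
            if cols > best_cols:
                best_cols = cols
                best_matches = matches
                best_ai0 = i
                best_ai1 = i_end
                best_bj0 = j
                best_bj1 = j_end
    return int(best), best_matches, best_cols, best_ai0, best_ai1, best_bj0, best_bj1
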