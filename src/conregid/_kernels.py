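"""Numba dynamic-programming kernels.

Two alignment kernels back the pipeline:

* ``profile_align`` — affine-gap profile-profile alignment with free terminal
  gaps (semi-global), used by the progressive multiple aligner.  Gap of
  length k costs ``open + k * extend`` in the interior.
* ``pssm_local_align`` — Smith-Waterman local alignment of a
  position-specific score matrix against an encoded sequence.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e30


@njit(cache=True)
def profile_align(S, gap_open, gap_extend):
    """Semi-global affine alignment over a column-pair score matrix ``S``.

    Returns ``(score, ops)`` where ``ops`` is an int8 array over
    {0: align both columns, 1: consume row-profile column (gap in other),
    2: consume column-profile column}.
    """
    L1, L2 = S.shape
    oe = gap_open + gap_extend
    e = gap_extend

    M = np.full((L1 + 1, L2 + 1), NEG)
    X = np.full((L1 + 1, L2 + 1), NEG)  # consumes profile 1 only
    Y = np.full((L1 + 1, L2 + 1), NEG)  # consumes profile 2 only
    PM = np.zeros((L1 + 1, L2 + 1), dtype=np.int8)
    PX = np.zeros((L1 + 1, L2 + 1), dtype=np.int8)
    PY = np.zeros((L1 + 1, L2 + 1), dtype=np.int8)

    M[0, 0] = 0.0
    for i in range(1, L1 + 1):
        X[i, 0] = 0.0  # free leading gap
        PX[i, 0] = 1
    for j in range(1, L2 + 1):
        Y[0, j] = 0.0
        PY[0, j] = 2

    for i in range(1, L1 + 1):
        for j in range(1, L2 + 1):
            # M: diagonal step
            best = M[i - 1, j - 1]
            src = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                src = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                src = 2
            M[i, j] = best + S[i - 1, j - 1]
            PM[i, j] = src
            # X: gap in profile 2
            a = M[i - 1, j] - oe
            b = X[i - 1, j] - e
            c = Y[i - 1, j] - oe
            if a >= b and a >= c:
                X[i, j] = a
                PX[i, j] = 0
            elif b >= c:
                X[i, j] = b
                PX[i, j] = 1
            else:
                X[i, j] = c
                PX[i, j] = 2
            # Y: gap in profile 1 (pointer codes are state ids: 0=M, 1=X, 2=Y)
            a = M[i, j - 1] - oe
            b = Y[i, j - 1] - e
            c = X[i, j - 1] - oe
            if a >= b and a >= c:
                Y[i, j] = a
                PY[i, j] = 0
            elif b >= c:
                Y[i, j] = b
                PY[i, j] = 2
            else:
                Y[i, j] = c
                PY[i, j] = 1

    # free trailing gaps: best cell on the last row or column
    bi, bj, bstate = L1, L2, 0
    bscore = M[L1, L2]
    if X[L1, L2] > bscore:
        bscore, bstate = X[L1, L2], 1
    if Y[L1, L2] > bscore:
        bscore, bstate = Y[L1, L2], 2
    for j in range(L2 + 1):
        for st in range(3):
            v = M[L1, j] if st == 0 else (X[L1, j] if st == 1 else Y[L1, j])
            if v > bscore:
                bscore, bi, bj, bstate = v, L1, j, st
    for i in range(L1 + 1):
        for st in range(3):
            v = M[i, L2] if st == 0 else (X[i, L2] if st == 1 else Y[i, L2])
            if v > bscore:
                bscore, bi, bj, bstate = v, i, L2, st

    ops = np.empty(L1 + L2, dtype=np.int8)
    n = 0
    # trailing free gaps
    for _ in range(L2 - bj):
        ops[n] = 2
        n += 1
    for _ in range(L1 - bi):
        ops[n] = 1
        n += 1
    i, j, st = bi, bj, bstate
    while i > 0 or j > 0:
        if st == 0:
            if i == 0 or j == 0:
                break
            src = PM[i, j]
            ops[n] = 0
            n += 1
            i -= 1
            j -= 1
            st = src
        elif st == 1:
            src = PX[i, j]
            ops[n] = 1
            n += 1
            i -= 1
            st = src if j > 0 else 1
        else:
            src = PY[i, j]
            ops[n] = 2
            n += 1
            j -= 1
            st = src if i > 0 else 2
    return bscore, ops[:n][::-1].copy()


@njit(cache=True)
def pssm_local_align(P, seq, gap_open, gap_extend):
    """Smith-Waterman of position-specific scores ``P`` (L x n_symbols)
    against an encoded sequence.

    Returns ``(score, p_start, p_end, s_start, s_end)`` with 0-based
    inclusive bounds; all -1 when the best score is 0.
    """
    L = P.shape[0]
    n = seq.shape[0]
    oe = gap_open + gap_extend
    e = gap_extend

    H = np.zeros((L + 1, n + 1))
    X = np.full((L + 1, n + 1), NEG)
    Y = np.full((L + 1, n + 1), NEG)
    # pointers: 0 stop, 1 diag from H, 2 from X, 3 from Y
    PH = np.zeros((L + 1, n + 1), dtype=np.int8)
    PX = np.zeros((L + 1, n + 1), dtype=np.int8)
    PY = np.zeros((L + 1, n + 1), dtype=np.int8)

    best = 0.0
    bi = -1
    bj = -1
    for i in range(1, L + 1):
        for j in range(1, n + 1):
            s = P[i - 1, seq[j - 1]]
            # gap states
            a = H[i - 1, j] - oe
            b = X[i - 1, j] - e
            if a >= b:
                X[i, j] = a
                PX[i, j] = 1
            else:
                X[i, j] = b
                PX[i, j] = 2
            a = H[i, j - 1] - oe
            b = Y[i, j - 1] - e
            if a >= b:
                Y[i, j] = a
                PY[i, j] = 1
            else:
                Y[i, j] = b
                PY[i, j] = 3
            diag = H[i - 1, j - 1] + s
            v = diag
            src = 1
            if X[i, j] > v:
                v = X[i, j]
                src = 2
            if Y[i, j] > v:
                v = Y[i, j]
                src = 3
            if v <= 0.0:
                v = 0.0
                src = 0
            H[i, j] = v
            PH[i, j] = src
            if v > best:
                best = v
                bi = i
                bj = j

    if best <= 0.0:
        return 0.0, -1, -1, -1, -1

    # traceback from (bi, bj) in state H; a local alignment starts and ends
    # on a diagonal step, so the last diagonal visited marks the start cell
    i, j = bi, bj
    state = 0  # 0 = H, 1 = X, 2 = Y
    si, sj = bi, bj
    while True:
        if state == 0:
            src = PH[i, j]
            if src == 0:
                break
            if src == 1:
                si, sj = i, j
                i -= 1
                j -= 1
            elif src == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            src = PX[i, j]
            i -= 1
            state = 0 if src == 1 else 1
        else:
            src = PY[i, j]
            j -= 1
            state = 0 if src == 1 else 2
    return best, si - 1, bi - 1, sj - 1, bj - 1
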