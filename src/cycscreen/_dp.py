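"""Dynamic-programming kernels (numba-compiled).

Two kernels live here:

* :func:`affine_align_matrix` — Gotoh global alignment over a precomputed
  column-pair score matrix, used for profile-profile merging in the
  progressive aligner.  A gap of length L costs ``open + (L - 1) * extend``.
* :func:`glocal_viterbi` — best-path score of a sequence against a
  position-specific profile, global in the model and local in the sequence.

Tracebacks prefer diagonal, then up (gap in the second profile), then left.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e30


@njit(cache=True)
def _gotoh_fill(S, gap_open, gap_extend):
    la, lb = S.shape
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # gap in B (consume A)
    Y = np.full((la + 1, lb + 1), NEG)  # gap in A (consume B)
    # traceback state: 0=M diag, 1=X, 2=Y; per-matrix predecessor flags
    tbM = np.zeros((la + 1, lb + 1), dtype=np.int8)
    tbX = np.zeros((la + 1, lb + 1), dtype=np.int8)
    tbY = np.zeros((la + 1, lb + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
        tbX[i, 0] = 0 if i == 1 else 1
    for j in range(1, lb + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
        tbY[0, j] = 0 if j == 1 else 2
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            # M: diagonal move from best of three
            best = M[i - 1, j - 1]
            state = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                state = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                state = 2
            M[i, j] = best + S[i - 1, j - 1]
            tbM[i, j] = state
            # X: gap in B
            o = M[i - 1, j] - gap_open
            e = X[i - 1, j] - gap_extend
            if o >= e:
                X[i, j] = o
                tbX[i, j] = 0
            else:
                X[i, j] = e
                tbX[i, j] = 1
            # Y: gap in A
            o = M[i, j - 1] - gap_open
            e = Y[i, j - 1] - gap_extend
            if o >= e:
                Y[i, j] = o
                tbY[i, j] = 0
            else:
                Y[i, j] = e
                tbY[i, j] = 2
    return M, X, Y, tbM, tbX, tbY


def affine_align_matrix(S: np.ndarray, gap_open: float, gap_extend: float):
    """Align the row space of S against its column space, globally.

    Returns ``(score, path)`` where path is a list of moves over (i, j):
    0 = diagonal (pair columns), 1 = consume a row of A (gap in B),
    2 = consume a column of B (gap in A).
    """
    S = np.ascontiguousarray(S, dtype=np.float64)
    M, X, Y, tbM, tbX, tbY = _gotoh_fill(S, float(gap_open), float(gap_extend))
    la, lb = S.shape
    # choose final state, preferring M then X then Y on ties
    finals = (M[la, lb], X[la, lb], Y[la, lb])
    state = int(np.argmax(finals))
    score = float(finals[state])
    i, j = la, lb
    path: list[int] = []
    while i > 0 or j > 0:
        if state == 0:
            prev = tbM[i, j]
            path.append(0)
            i -= 1
            j -= 1
        elif state == 1:
            prev = tbX[i, j]
            path.append(1)
            i -= 1
        else:
            prev = tbY[i, j]
            path.append(2)
            j -= 1
        state = int(prev)
    path.reverse()
    return score, path


@njit(cache=True)
def glocal_viterbi(em, seq_idx, insert_open, insert_extend, delete_open, delete_extend):
    """Best glocal alignment score in bits.

    ``em`` is (L, 20) match-state emission log-odds; ``seq_idx`` holds
    residue indices (negative = unknown, emitting log-odds 0).  The model
    must be traversed end to end (match or delete states); unaligned
    sequence flanks are free.
    """
    L = em.shape[0]
    N = seq_idx.shape[0]
    M = np.full((L + 1, N + 1), NEG)
    I = np.full((L + 1, N + 1), NEG)
    D = np.full((L + 1, N + 1), NEG)
    # start: model position 0, any sequence prefix consumed for free
    for j in range(N + 1):
        M[0, j] = 0.0
    D[1, 0] = -delete_open
    for i in range(2, L + 1):
        D[i, 0] = D[i - 1, 0] - delete_extend
    for i in range(1, L + 1):
        for j in range(1, N + 1):
            a = seq_idx[j - 1]
            e = em[i - 1, a] if a >= 0 else 0.0
            best = M[i - 1, j - 1]
            if I[i - 1, j - 1] > best:
                best = I[i - 1, j - 1]
            if D[i - 1, j - 1] > best:
                best = D[i - 1, j - 1]
            M[i, j] = best + e
            # insert between model columns i and i+1 (emits background)
            o = M[i, j - 1] - insert_open
            x = I[i, j - 1] - insert_extend
            I[i, j] = o if o >= x else x
            # delete model column i
            o = M[i - 1, j] - delete_open
            x = D[i - 1, j] - delete_extend
            D[i, j] = o if o >= x else x
    best = NEG
    for j in range(N + 1):
        if M[L, j] > best:
            best = M[L, j]
        if D[L, j] > best:
            best = D[L, j]
    return best
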