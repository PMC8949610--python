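"""Numba dynamic-programming kernels for local alignment.

Two kernels:

* :func:`sw_traceback` — full Smith–Waterman with affine gaps (Gotoh
  recurrences) and a deterministic traceback, used as the testing oracle.
* :func:`extend_xdrop` — banded, X-drop-terminated extension alignment
  anchored at a seed, used by the production seed-and-extend engine.

Sequences enter as uint8 code arrays (A=0, C=1, G=2, T=3, N=4); an N never
matches anything, including another N.

Gap convention: a gap of length L costs ``gap_open + L * gap_extend``.

Traceback tie order is fixed (diagonal > up > left, where "up" consumes a
base of the first sequence) so outputs are deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.int32(-(10**9) // 2)

# op codes emitted by tracebacks
OP_DIAG = 0  # consume one base of each sequence
OP_UP = 1    # consume a base of `a` only (gap in `b`)
OP_LEFT = 2  # consume a base of `b` only (gap in `a`)


@njit(cache=True)
def sw_traceback(a, b, match, mismatch, gap_open, gap_ext):
    """Optimal local alignment of code arrays `a` vs `b`.

    Returns (score, a_start, a_end, b_start, b_end, ops) where ops is an
    int8 array of OP_* codes along the alignment (empty when score < 1).
    The best cell is the first maximum in row-major scan order; the
    traceback resolves ties diagonal > up > left.
    """
    n = a.shape[0]
    m = b.shape[0]
    H = np.zeros((n + 1, m + 1), np.int32)
    E = np.full((n + 1, m + 1), NEG, np.int32)
    F = np.full((n + 1, m + 1), NEG, np.int32)
    go = gap_open + gap_ext
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            e = H[i - 1, j] - go
            if E[i - 1, j] - gap_ext > e:
                e = E[i - 1, j] - gap_ext
            E[i, j] = e
            f = H[i, j - 1] - go
            if F[i, j - 1] - gap_ext > f:
                f = F[i, j - 1] - gap_ext
            F[i, j] = f
            s = match if (ai == b[j - 1] and ai < 4) else mismatch
            h = H[i - 1, j - 1] + s
            if h < e:
                h = e
            if h < f:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    if best < 1:
        return 0, 0, 0, 0, 0, np.empty(0, np.int8)
    ops = np.empty(bi + bj, np.int8)
    k = ops.shape[0]
    i = bi
    j = bj
    state = 0  # 0=H, 1=E, 2=F
    while True:
        if state == 0:
            if H[i, j] == 0:
                break
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] < 4) else mismatch
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + s:
                k -= 1
                ops[k] = OP_DIAG
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            k -= 1
            ops[k] = OP_UP
            if E[i, j] == H[i - 1, j] - go:
                state = 0
            i -= 1
        else:
            k -= 1
            ops[k] = OP_LEFT
            if F[i, j] == H[i, j - 1] - go:
                state = 0
            j -= 1
    return int(best), i, bi, j, bj, ops[k:]


@njit(cache=True)
def extend_xdrop_score(a, b, match, mismatch, gap_open, gap_ext, x_drop, band):
    """Score-only X-drop extension anchored at (0, 0): rolling two-row DP.

    Same recurrences and band as :func:`extend_xdrop` but O(band) memory and
    no traceback; returns (score, a_consumed, b_consumed).  Used to vet
    chains cheaply before paying for the traceback matrices.
    """
    n = a.shape[0]
    m = b.shape[0]
    width = 2 * band + 1
    go = gap_open + gap_ext
    h_prev = np.full(width, NEG, np.int32)
    e_prev = np.full(width, NEG, np.int32)
    h_cur = np.full(width, NEG, np.int32)
    e_cur = np.full(width, NEG, np.int32)
    h_prev[band] = 0
    jmax0 = m if m < band else band
    acc = np.int32(0)
    for j in range(1, jmax0 + 1):
        acc = -(gap_open + j * gap_ext)
        h_prev[j + band] = acc
    best = np.int32(0)
    bi = 0
    bj = 0
    nrows = n if n < m + band else m + band
    for i in range(1, nrows + 1):
        ai = a[i - 1]
        lo = i - band
        if lo < 0:
            lo = 0
        hi = i + band
        if hi > m:
            hi = m
        if lo > hi:
            break
        row_best = NEG
        f = NEG
        for j in range(lo, hi + 1):
            o = j - i + band
            e = NEG
            if o + 1 < width:
                e = h_prev[o + 1] - go
                if e_prev[o + 1] - gap_ext > e:
                    e = e_prev[o + 1] - gap_ext
            e_cur[o] = e
            if o - 1 >= 0 and j > 0:
                fh = h_cur[o - 1] - go
                if f - gap_ext > fh:
                    f = f - gap_ext
                else:
                    f = fh
            else:
                f = NEG
            h = NEG
            if j > 0:
                hd = h_prev[o]
                if hd > NEG:
                    s = match if (ai == b[j - 1] and ai < 4) else mismatch
                    h = hd + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < best - x_drop:
                h = NEG
            h_cur[o] = h
            if h > row_best:
                row_best = h
            if h > best:
                best = h
                bi = i
                bj = j
        if row_best <= best - x_drop or row_best == NEG:
            break
        tmp = h_prev
        h_prev = h_cur
        h_cur = tmp
        tmp = e_prev
        e_prev = e_cur
        e_cur = tmp
        h_cur[:] = NEG
        e_cur[:] = NEG
    return int(best), bi, bj


@njit(cache=True)
def extend_xdrop(a, b, match, mismatch, gap_open, gap_ext, x_drop, band):
    """Banded extension alignment anchored at (0, 0).

    Finds the best-scoring path that starts immediately before ``a[0]``/
    ``b[0]`` and ends anywhere, restricted to the band ``|i - j| <= band``.
    Rows whose every in-band cell falls more than ``x_drop`` below the best
    score seen so far terminate the extension (BLAST-style X-drop).

    Returns (score, a_consumed, b_consumed, ops).  Score can be 0 with an
    empty path when no positive-scoring extension exists.
    """
    n = a.shape[0]
    m = b.shape[0]
    width = 2 * band + 1
    nrows = n if n < m + band else m + band
    go = gap_open + gap_ext
    H = np.full((nrows + 1, width), NEG, np.int32)
    E = np.full((nrows + 1, width), NEG, np.int32)
    F = np.full((nrows + 1, width), NEG, np.int32)
    # offset o = j - i + band
    H[0, band] = 0
    # leading horizontal gaps along row 0
    jmax0 = m if m < band else band
    for j in range(1, jmax0 + 1):
        F[0, j + band] = -(gap_open + j * gap_ext)
        H[0, j + band] = F[0, j + band]
    best = np.int32(0)
    bi = 0
    bj = 0
    last_row = 0
    for i in range(1, nrows + 1):
        ai = a[i - 1]
        lo = i - band
        if lo < 0:
            lo = 0
        hi = i + band
        if hi > m:
            hi = m
        if lo > hi:
            break
        row_best = NEG
        for j in range(lo, hi + 1):
            o = j - i + band
            # vertical: from (i-1, j) => prev row offset o+1
            e = NEG
            if o + 1 < width:
                hv = H[i - 1, o + 1]
                ev = E[i - 1, o + 1]
                e = hv - go
                if ev - gap_ext > e:
                    e = ev - gap_ext
            E[i, o] = e
            # horizontal: from (i, j-1) => same row offset o-1
            f = NEG
            if o - 1 >= 0 and j > 0:
                hh = H[i, o - 1]
                fh = F[i, o - 1]
                f = hh - go
                if fh - gap_ext > f:
                    f = fh - gap_ext
            F[i, o] = f
            h = NEG
            if j > 0:
                hd = H[i - 1, o]  # diagonal keeps the same offset
                if hd > NEG:
                    s = match if (ai == b[j - 1] and ai < 4) else mismatch
                    h = hd + s
            else:
                # j == 0: pure vertical prefix gap
                h = NEG
            if e > h:
                h = e
            if f > h:
                h = f
            if h < best - x_drop:
                h = NEG  # X-drop prune
            H[i, o] = h
            if h > row_best:
                row_best = h
            if h > best:
                best = h
                bi = i
                bj = j
        last_row = i
        if row_best <= best - x_drop or row_best == NEG:
            break
    if best < 1:
        return 0, 0, 0, np.empty(0, np.int8)
    ops = np.empty(bi + bj, np.int8)
    k = ops.shape[0]
    i = bi
    j = bj
    state = 0
    while i > 0 or j > 0:
        o = j - i + band
        if state == 0:
            h = H[i, o]
            took = False
            if i > 0 and j > 0:
                s = match if (a[i - 1] == b[j - 1] and a[i - 1] < 4) else mismatch
                if H[i - 1, o] > NEG and h == H[i - 1, o] + s:
                    k -= 1
                    ops[k] = OP_DIAG
                    i -= 1
                    j -= 1
                    took = True
            if not took:
                if h == E[i, o]:
                    state = 1
                else:
                    state = 2
        elif state == 1:
            k -= 1
            ops[k] = OP_UP
            if o + 1 < width and E[i, o] == H[i - 1, o + 1] - go:
                state = 0
            i -= 1
        else:
            k -= 1
            ops[k] = OP_LEFT
            if o - 1 >= 0 and F[i, o] == H[i, o - 1] - go:
                state = 0
            j -= 1
    return int(best), bi, bj, ops[k:]
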