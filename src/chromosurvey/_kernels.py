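"""Numba kernels for banded affine-gap local alignment and RNA folding.

The alignment band is expressed in diagonal coordinates d = j - i (query
index i, subject index j, both 0-based); cells outside [d_lo, d_hi] are
unreachable.  A full Smith-Waterman is the special case d_lo = -len(q),
d_hi = len(s).
"""
from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1_000_000_000


@njit(cache=True)
def banded_align(q, s, submat, gap_open, gap_ext, d_lo, d_hi):
    """Local alignment of code arrays q vs s restricted to a diagonal band.

    gap_open / gap_ext are positive costs; the first residue of a gap costs
    gap_open + gap_ext (BLAST convention).  Returns
    (score, q_start, q_end, s_start, s_end, n_ident, n_pos, n_mismatch,
     n_gap_open, n_gap_cols, aln_len) with half-open 0-based intervals.
    """
    m = q.shape[0]
    n = s.shape[0]
    if d_lo < -m:
        d_lo = -m
    if d_hi > n:
        d_hi = n
    W = d_hi - d_lo + 1
    if W <= 0 or m == 0 or n == 0:
        return (0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0)
    go = gap_open + gap_ext
    ge = gap_ext

    H = np.full((m + 1, W), NEG, dtype=np.int32)
    E = np.full((m + 1, W), NEG, dtype=np.int32)
    F = np.full((m + 1, W), NEG, dtype=np.int32)
    # pointers: ptrH 0=stop,1=diag,2=fromE,3=fromF ; ptrE/ptrF 1=open,0=extend
    ptrH = np.zeros((m + 1, W), dtype=np.uint8)
    ptrE = np.zeros((m + 1, W), dtype=np.uint8)
    ptrF = np.zeros((m + 1, W), dtype=np.uint8)

    for k in range(W):
        j = d_lo + k
        if 0 <= j <= n:
            H[0, k] = 0
    best = 0
    bi = 0
    bk = 0
    for i in range(1, m + 1):
        # valid columns: 1 <= j <= n with j = i + d_lo + k
        k_lo = 1 - (i + d_lo)
        if k_lo < 0:
            k_lo = 0
        k_hi = n - (i + d_lo)
        if k_hi > W - 1:
            k_hi = W - 1
        k0 = -(i + d_lo)          # column j == 0, a free start point
        if 0 <= k0 < W:
            H[i, k0] = 0
        for k in range(k_lo, k_hi + 1):
            j = i + d_lo + k
            e = NEG
            pe = np.uint8(0)
            if k - 1 >= 0:
                h_prev = H[i, k - 1]
                e_prev = E[i, k - 1]
                if h_prev - go >= e_prev - ge:
                    e = h_prev - go
                    pe = 1
                else:
                    e = e_prev - ge
                    pe = 0
            E[i, k] = e
            ptrE[i, k] = pe
            f = NEG
            pf = np.uint8(0)
            if k + 1 < W:
                h_prev = H[i - 1, k + 1]
                f_prev = F[i - 1, k + 1]
                if h_prev - go >= f_prev - ge:
                    f = h_prev - go
                    pf = 1
                else:
                    f = f_prev - ge
                    pf = 0
            F[i, k] = f
            ptrF[i, k] = pf
            d = NEG
            if H[i - 1, k] > NEG:
                d = H[i - 1, k] + submat[q[i - 1], s[j - 1]]
            h = 0
            p = np.uint8(0)
            if d > h:
                h = d
                p = 1
            if e > h:
                h = e
                p = 2
            if f > h:
                h = f
                p = 3
            H[i, k] = h
            ptrH[i, k] = p
            if h > best:
                best = h
                bi = i
                bk = k
    if best <= 0:
        return (0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0)

    i = bi
    k = bk
    q_end = bi
    s_end = bi + d_lo + bk
    n_ident = 0
    n_pos = 0
    n_mis = 0
    n_gopen = 0
    n_gcols = 0
    aln_len = 0
    state = 0
    while True:
        if state == 0:
            p = ptrH[i, k]
            if p == 0:
                break
            if p == 1:
                j = i + d_lo + k
                sc = submat[q[i - 1], s[j - 1]]
                aln_len += 1
                if q[i - 1] == s[j - 1]:
                    n_ident += 1
                    n_pos += 1
                elif sc > 0:
                    n_pos += 1
                    n_mis += 1
                else:
                    n_mis += 1
                i -= 1
                continue
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:          # in E: gap in query, consume subject col
            pe = ptrE[i, k]
            aln_len += 1
            n_gcols += 1
            k -= 1
            if pe == 1:
                n_gopen += 1
                state = 0
        else:                     # in F: gap in subject, consume query row
            pf = ptrF[i, k]
            aln_len += 1
            n_gcols += 1
            i -= 1
            k += 1
            if pf == 1:
                n_gopen += 1
                state = 0
    q_start = i
    s_start = i + d_lo + k
    return (best, q_start, q_end, s_start, s_end,
            n_ident, n_pos, n_mis, n_gopen, n_gcols, aln_len)


@njit(cache=True)
def expand_ranges(lo, hi):
    """Concatenate [lo[i], hi[i]) ranges into one index array."""
    total = 0
    for i in range(lo.shape[0]):
        total += hi[i] - lo[i]
    out = np.empty(total, dtype=np.int64)
    src = np.empty(total, dtype=np.int64)
    p = 0
    for i in range(lo.shape[0]):
        for v in range(lo[i], hi[i]):
            out[p] = v
            src[p] = i
            p += 1
    return out, src


@njit(cache=True)
def fold_energy(codes, pair_e, bulge_pen, max_internal, min_loop,
                hairpin_pen, multi_pen):
    """Minimum-energy nested secondary structure (Zuker-lite).

    codes: 0=A,1=C,2=G,3=U, >=4 unpairable.  pair_e is a 4x4 matrix of pair
    energies (negative for allowed pairs, huge for disallowed).  Unpaired
    bases inside internal loops/bulges cost +bulge_pen each; hairpin and
    exterior/multiloop unpaired bases are free; hairpin loop >= min_loop.
    Returns (mfe, V, W, W1); V[i,j] requires (i,j) paired, W1 requires at
    least one pair.
    """
    n = codes.shape[0]
    INF = 1.0e9
    V = np.full((n, n), INF, dtype=np.float64)
    Wm = np.zeros((n, n), dtype=np.float64)
    W1 = np.full((n, n), INF, dtype=np.float64)
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            ci = codes[i]
            cj = codes[j]
            pe = INF
            if ci < 4 and cj < 4:
                pe = pair_e[ci, cj]
            if pe < INF and j - i - 1 >= min_loop:
                best = hairpin_pen
                for k in range(i + 1, j - 1):
                    lo = k - i - 1
                    if lo > max_internal:
                        break
                    for l in range(j - 1, k, -1):
                        ro = j - l - 1
                        if lo + ro > max_internal:
                            break
                        v_in = V[k, l]
                        if v_in < INF:
                            cand = v_in + bulge_pen * (lo + ro)
                            if cand < best:
                                best = cand
                for mdx in range(i + 1, j - 1):
                    a = W1[i + 1, mdx]
                    b = W1[mdx + 1, j - 1]
                    if a < INF and b < INF:
                        cand = a + b + multi_pen
                        if cand < best:
                            best = cand
                V[i, j] = pe + best
            w1 = W1[i, j - 1]
            for k in range(i, j):
                left = 0.0 if k == i else Wm[i, k - 1]
                if V[k, j] < INF:
                    cand = left + V[k, j]
                    if cand < w1:
                        w1 = cand
            W1[i, j] = w1
            w = Wm[i, j - 1]
            if w1 < w:
                w = w1
            Wm[i, j] = w
    mfe = Wm[0, n - 1] if n > 0 else 0.0
    if mfe > 0.0:
        mfe = 0.0
    return mfe, V, Wm, W1
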