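"""Numba kernels for pairwise/profile alignment, distances and neighbor joining.

All kernels operate on int8-encoded sequences (A=0,C=1,G=2,T=3,N=4) and are
deliberately free of Python objects so they compile with ``nopython=True``.
Gap cost convention: a gap of length k costs open + k*ext.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e18


@njit(cache=True)
def _subst(a, b, match, mismatch):
    if a == 4 or b == 4:  # N never matches anything, including N
        return mismatch
    return match if a == b else mismatch


@njit(cache=True)
def sw_end_scores(q, t, match, mismatch, gap_open, gap_ext):
    """Best local-alignment score ending at each target position.

    Returns an array ``best[j]`` = max over query positions of H[i, j].
    O(len(q)) memory; used to seed candidate hit locations in long targets.
    """
    m = q.shape[0]
    n = t.shape[0]
    Hprev = np.zeros(m + 1, dtype=np.float64)
    Hcur = np.zeros(m + 1, dtype=np.float64)
    Eprev = np.full(m + 1, NEG, dtype=np.float64)
    Ecur = np.full(m + 1, NEG, dtype=np.float64)
    best = np.zeros(n, dtype=np.float64)
    go = gap_open + gap_ext
    for j in range(1, n + 1):
        Hcur[0] = 0.0
        Ecur[0] = NEG
        f = NEG  # vertical gap state, runs along i within this column
        colbest = 0.0
        for i in range(1, m + 1):
            e = max(Hprev[i] - go, Eprev[i] - gap_ext)
            f = max(Hcur[i - 1] - go, f - gap_ext)
            h = Hprev[i - 1] + _subst(q[i - 1], t[j - 1], match, mismatch)
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            Hcur[i] = h
            Ecur[i] = e
            if h > colbest:
                colbest = h
        best[j - 1] = colbest
        Hprev, Hcur = Hcur, Hprev
        Eprev, Ecur = Ecur, Eprev
    return best


@njit(cache=True)
def sw_align(q, t, match, mismatch, gap_open, gap_ext):
    """Optimal local alignment with affine gaps and full traceback.

    Returns (score, q_start, q_end, t_start, t_end, ops) where ops is an
    int8 array over aligned columns: 0 = match/mismatch, 1 = gap in target
    (query char consumed), 2 = gap in query (target char consumed).
    Tie-breaking is deterministic: among equal-scoring end cells the one with
    the smallest target end, then smallest query end, wins; traceback prefers
    diagonal, then gap-in-target, then gap-in-query.
    """
    m = q.shape[0]
    n = t.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.float64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.float64)
    F = np.full((m + 1, n + 1), NEG, dtype=np.float64)
    go = gap_open + gap_ext
    best = 0.0
    bi = 0
    bj = 0
    for j in range(1, n + 1):
        for i in range(1, m + 1):
            e = max(H[i, j - 1] - go, E[i, j - 1] - gap_ext)
            f = max(H[i - 1, j] - go, F[i - 1, j] - gap_ext)
            h = H[i - 1, j - 1] + _subst(q[i - 1], t[j - 1], match, mismatch)
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
            if h > best:
                best = h
                bi = i
                bj = j
    if best <= 0.0:
        return 0.0, 0, 0, 0, 0, np.empty(0, dtype=np.int8)
    # scan for smallest (t_end, q_end) achieving best
    done = False
    for j in range(1, n + 1):
        for i in range(1, m + 1):
            if H[i, j] == best:
                bi = i
                bj = j
                done = True
                break
        if done:
            break
    ops = np.empty(m + n, dtype=np.int8)
    k = 0
    i = bi
    j = bj
    state = 0  # 0 = in H, 1 = in E (gap in query dir along target), 2 = in F
    while i > 0 and j > 0:
        if state == 0:
            h = H[i, j]
            if h == 0.0:
                break
            diag = H[i - 1, j - 1] + _subst(q[i - 1], t[j - 1], match, mismatch)
            if h == diag:
                ops[k] = 0
                k += 1
                i -= 1
                j -= 1
            elif h == F[i, j]:
                state = 2
            else:
                state = 1
        elif state == 1:  # E: gap in query, consumes target char
            ops[k] = 2
            k += 1
            if E[i, j] == E[i, j - 1] - gap_ext:
                j -= 1
            else:
                j -= 1
                state = 0
        else:  # F: gap in target, consumes query char
            ops[k] = 1
            k += 1
            if F[i, j] == F[i - 1, j] - gap_ext:
                i -= 1
            else:
                i -= 1
                state = 0
    out = ops[:k][::-1].copy()
    return best, i, bi, j, bj, out


@njit(cache=True)
def profile_align(pa, pb, gap_open, gap_ext, match, mismatch):
    """Global profile-profile alignment (Needleman-Wunsch, affine gaps).

    pa, pb: (len, 5) float profiles (A,C,G,T,gap frequencies per column).
    Column score = sum over residue pairs of fa*fb*(match or mismatch);
    gap-open penalties are scaled down against gap-rich columns. Returns an
    int8 ops array (0 diagonal, 1 gap in pb, 2 gap in pa).
    """
    m = pa.shape[0]
    n = pb.shape[0]
    go = gap_open + gap_ext
    H = np.empty((m + 1, n + 1), dtype=np.float64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.float64)
    F = np.full((m + 1, n + 1), NEG, dtype=np.float64)
    H[0, 0] = 0.0
    for j in range(1, n + 1):
        E[0, j] = -go - (j - 1) * gap_ext
        H[0, j] = E[0, j]
    for i in range(1, m + 1):
        F[i, 0] = -go - (i - 1) * gap_ext
        H[i, 0] = F[i, 0]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            # expected substitution score between the two columns
            s = 0.0
            occ = 0.0
            for x in range(4):
                fa = pa[i - 1, x]
                if fa == 0.0:
                    continue
                for y in range(4):
                    fb = pb[j - 1, y]
                    if fb == 0.0:
                        continue
                    s += fa * fb * (match if x == y else mismatch)
                    occ += fa * fb
            # columns rich in existing gaps contribute less signal
            e = max(H[i, j - 1] - go * (1.0 - pb[j - 1, 4]) - gap_ext,
                    E[i, j - 1] - gap_ext)
            f = max(H[i - 1, j] - go * (1.0 - pa[i - 1, 4]) - gap_ext,
                    F[i - 1, j] - gap_ext)
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
    ops = np.empty(m + n, dtype=np.int8)
    k = 0
    i = m
    j = n
    while i > 0 or j > 0:
        if i > 0 and j > 0 and H[i, j] != E[i, j] and H[i, j] != F[i, j]:
            ops[k] = 0
            i -= 1
            j -= 1
        elif i > 0 and (j == 0 or H[i, j] == F[i, j]):
            ops[k] = 1
            i -= 1
        else:
            ops[k] = 2
            j -= 1
        k += 1
    return ops[:k][::-1].copy()


@njit(cache=True)
def pair_counts(rows, cols, i, j):
    """Pairwise-deletion substitution counts between rows i and j of an
    int8 MSA over the given column index array.

    Returns (valid, diff, transitions, transversions, gc_count, total_bases).
    """
    valid = 0
    diff = 0
    ts = 0
    tv = 0
    gc = 0
    for c in range(cols.shape[0]):
        a = rows[i, cols[c]]
        b = rows[j, cols[c]]
        if a > 3 or b > 3:
            continue
        valid += 1
        if a == 1 or a == 2:
            gc += 1
        if b == 1 or b == 2:
            gc += 1
        if a != b:
            diff += 1
            # transitions: A<->G (0,2), C<->T (1,3)
            if (a + b == 2 and a != 1) or (a + b == 4 and a != 2):
                ts += 1
            else:
                tv += 1
    return valid, diff, ts, tv, gc, 2 * valid


@njit(cache=True)
def distance_matrix_kernel(rows, cols, model):
    """All-pairs distances under pairwise deletion.

    model: 0 = p-distance, 1 = Kimura 2-parameter, 2 = Tamura-Nei-form
    composite-likelihood surrogate with empirical (pooled) base frequencies.
    Saturated (log-domain-failing) pairs fall back to p-distance.
    """
    nseq = rows.shape[0]
    D = np.zeros((nseq, nseq), dtype=np.float64)
    # pooled base frequencies over used columns (MCL pools across the MSA)
    freq = np.zeros(4, dtype=np.float64)
    for i in range(nseq):
        for c in range(cols.shape[0]):
            a = rows[i, cols[c]]
            if a <= 3:
                freq[a] += 1.0
    tot = freq.sum()
    if tot > 0:
        freq = freq / tot
    gR = freq[0] + freq[2]
    gY = freq[1] + freq[3]
    k1d = 2.0 * freq[0] * freq[2] / gR if gR > 0 else 0.0
    k2d = 2.0 * freq[1] * freq[3] / gY if gY > 0 else 0.0
    k3d = 2.0 * (gR * gY - freq[0] * freq[2] * gY / gR - freq[1] * freq[3] * gR / gY) \
        if (gR > 0 and gY > 0) else 0.0
    for i in range(nseq):
        for j in range(i + 1, nseq):
            valid, diff, ts, tv, _gc, _tb = pair_counts(rows, cols, i, j)
            if valid == 0:
                D[i, j] = np.nan
                D[j, i] = np.nan
                continue
            p = diff / valid
            if model == 0:
                d = p
            elif model == 1:
                P = ts / valid
                Q = tv / valid
                w1 = 1.0 - 2.0 * P - Q
                w2 = 1.0 - 2.0 * Q
                if w1 <= 0.0 or w2 <= 0.0:
                    d = p  # saturation fallback
                else:
                    d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
            else:
                # Tamura-Nei form with pooled frequencies; transitions are
                # split between purine and pyrimidine classes proportionally.
                P1 = 0.0
                P2 = 0.0
                Q = tv / valid
                # count purine vs pyrimidine transitions
                for c in range(cols.shape[0]):
                    a = rows[i, cols[c]]
                    b = rows[j, cols[c]]
                    if a > 3 or b > 3 or a == b:
                        continue
                    if (a == 0 and b == 2) or (a == 2 and b == 0):
                        P1 += 1.0
                    elif (a == 1 and b == 3) or (a == 3 and b == 1):
                        P2 += 1.0
                P1 /= valid
                P2 /= valid
                w1 = 1.0 - P1 / k1d - 0.5 * Q / gR if k1d > 0 else -1.0
                w2 = 1.0 - P2 / k2d - 0.5 * Q / gY if k2d > 0 else -1.0
                w3 = 1.0 - 0.5 * Q / (gR * gY) if gR * gY > 0 else -1.0
                if w1 <= 0.0 or w2 <= 0.0 or w3 <= 0.0:
                    d = p
                else:
                    d = -k1d * np.log(w1) - k2d * np.log(w2) - k3d * np.log(w3)
            D[i, j] = d
            D[j, i] = d
    return D


@njit(cache=True)
def nj_kernel(D0):
    """Saitou-Nei neighbor joining.

    Returns (left, right, lblen, rblen) arrays describing 2n-2 nodes:
    nodes 0..n-1 are leaves; node k>=n joins children left[k], right[k] with
    branch lengths lblen[k], rblen[k]. The final node is the root placed on
    the last remaining edge (its two children carry the split edge length).
    Ties in the Q criterion resolve to the smallest (i, j) label pair.
    Negative branch lengths are truncated to 0 with the deficit moved to the
    sister branch.
    """
    n = D0.shape[0]
    total = 2 * n
    left = np.full(total, -1, dtype=np.int64)
    right = np.full(total, -1, dtype=np.int64)
    lblen = np.zeros(total, dtype=np.float64)
    rblen = np.zeros(total, dtype=np.float64)
    if n == 2:
        left[2] = 0
        right[2] = 1
        lblen[2] = D0[0, 1] / 2.0
        rblen[2] = D0[0, 1] / 2.0
        return left[: n + 1], right[: n + 1], lblen[: n + 1], rblen[: n + 1]
    D = np.zeros((total, total), dtype=np.float64)
    D[:n, :n] = D0
    active = np.zeros(total, dtype=np.int8)
    active[:n] = 1
    nact = n
    nxt = n
    while nact > 3:
        idx = np.where(active == 1)[0]
        r = np.zeros(idx.shape[0], dtype=np.float64)
        for a in range(idx.shape[0]):
            s = 0.0
            for b in range(idx.shape[0]):
                s += D[idx[a], idx[b]]
            r[a] = s
        bestq = 1.0e300
        ba = -1
        bb = -1
        for a in range(idx.shape[0]):
            for b in range(a + 1, idx.shape[0]):
                qv = (nact - 2) * D[idx[a], idx[b]] - r[a] - r[b]
                if qv < bestq - 1e-12:
                    bestq = qv
                    ba = a
                    bb = b
        i = idx[ba]
        j = idx[bb]
        li = 0.5 * D[i, j] + (r[ba] - r[bb]) / (2.0 * (nact - 2))
        lj = D[i, j] - li
        # truncate negatives, shifting deficit to the sister branch
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
            if li < 0.0:
                li = 0.0
        left[nxt] = i
        right[nxt] = j
        lblen[nxt] = li
        rblen[nxt] = lj
        for a in range(idx.shape[0]):
            k = idx[a]
            if k == i or k == j:
                continue
            D[nxt, k] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
            if D[nxt, k] < 0.0:
                D[nxt, k] = 0.0
            D[k, nxt] = D[nxt, k]
        active[i] = 0
        active[j] = 0
        active[nxt] = 1
        nact -= 1
        nxt += 1
    # resolve the final three nodes with the three-point formulas
    idx = np.where(active == 1)[0]
    a = idx[0]
    b = idx[1]
    c = idx[2]
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    if la < 0.0:
        la = 0.0
    if lb < 0.0:
        lb = 0.0
    if lc < 0.0:
        lc = 0.0
    # join a,b first, then attach c at the root
    left[nxt] = a
    right[nxt] = b
    lblen[nxt] = la
    rblen[nxt] = lb
    left[nxt + 1] = nxt
    right[nxt + 1] = c
    lblen[nxt + 1] = 0.0
    rblen[nxt + 1] = lc
    return left[: nxt + 2], right[: nxt + 2], lblen[: nxt + 2], rblen[: nxt + 2]
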