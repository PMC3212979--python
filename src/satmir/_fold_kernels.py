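"""Numba kernels for RNA secondary-structure prediction.

Energy model (kcal/mol), shared by the MFE and partition kernels and by the
exhaustive-enumeration oracle used in tests:

* allowed pairs: AU, UA, CG, GC, GU, UG; minimum hairpin loop 3 nt
* hairpin loop of size l:      4.8 + 1.08 * ln(l/3)
* stack (no unpaired between): -0.9 - (w_outer + w_inner)/2 with pair
  strengths w(CG/GC) = 2.0, w(AU/UA) = 1.3, w(GU/UG) = 0.8
* interior loop / bulge with side lengths l1, l2 (1 <= l1+l2 <= 30):
  1.6 + 0.45*(l1+l2) + 0.65*|l1-l2|; loops with l1+l2 > 30 are disallowed
* multiloop: 3.4 + 0.4 per branch (closing pair included), unpaired free
* exterior bases free

Energies are temperature-independent structural constants; temperature enters
only through the Boltzmann factor RT in the partition function. The partition
kernel works in a linearly rescaled domain (a factor 1/kappa per nucleotide)
so that Z never overflows for long sequences; log Z is recovered exactly.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MINLOOP = 3
MAXINTER = 30
ML_A = 3.4
ML_B = 0.4
INF = 1.0e9

# pair type indices: 0 CG, 1 GC, 2 GU, 3 UG, 4 AU, 5 UA
_PT = np.full((4, 4), -1, dtype=np.int8)
_PT[1, 2] = 0
_PT[2, 1] = 1
_PT[2, 3] = 2
_PT[3, 2] = 3
_PT[0, 3] = 4
_PT[3, 0] = 5
_W = np.array([2.0, 2.0, 0.8, 0.8, 1.3, 1.3])


@njit(cache=True)
def pair_type(a, b):
    if a > 3 or b > 3:
        return -1
    return _PT[a, b]


@njit(cache=True)
def e_hairpin(l):
    return 4.8 + 1.08 * np.log(l / 3.0)


@njit(cache=True)
def e_stack(pt_out, pt_in):
    return -0.9 - 0.5 * (_W[pt_out] + _W[pt_in])


@njit(cache=True)
def e_interior(l1, l2):
    s = l1 + l2
    d = l1 - l2
    if d < 0:
        d = -d
    return 1.6 + 0.45 * s + 0.65 * d


@njit(cache=True)
def mfe_kernel(s):
    """Zuker-style MFE fold. Returns (energy, partner) with partner[i] = j or -1.

    Traceback ties resolve toward the 5'-most pairing: the exterior traceback
    prefers the pair with the smallest start, closed-structure cases are
    evaluated hairpin, then interior (k ascending, l descending), then
    multiloop (k ascending).
    """
    n = s.shape[0]
    partner = np.full(n, -1, dtype=np.int64)
    if n < MINLOOP + 2:
        return 0.0, partner
    V = np.full((n, n), INF, dtype=np.float64)
    WM = np.full((n, n), INF, dtype=np.float64)
    WM1 = np.full((n, n), INF, dtype=np.float64)
    for span in range(MINLOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            pt = pair_type(s[i], s[j])
            if pt >= 0:
                best = e_hairpin(j - i - 1)
                kmax = j - 1
                for k in range(i + 1, kmax):
                    l1 = k - i - 1
                    if l1 > MAXINTER:
                        break
                    for l in range(j - 1, k + MINLOOP, -1):
                        l2 = j - l - 1
                        if l1 + l2 > MAXINTER:
                            break
                        if V[k, l] >= INF:
                            continue
                        pt2 = pair_type(s[k], s[l])
                        if pt2 < 0:
                            continue
                        if l1 == 0 and l2 == 0:
                            e = e_stack(pt, pt2) + V[k, l]
                        else:
                            e = e_interior(l1, l2) + V[k, l]
                        if e < best:
                            best = e
                # multiloop
                for k in range(i + 2, j - 1):
                    if WM[i + 1, k - 1] < INF and WM1[k, j - 1] < INF:
                        e = ML_A + ML_B + WM[i + 1, k - 1] + WM1[k, j - 1]
                        if e < best:
                            best = e
                V[i, j] = best
            # WM1
            w = WM1[i, j - 1] if j - 1 > i else INF
            if V[i, j] + ML_B < w:
                w = V[i, j] + ML_B
            WM1[i, j] = w
            # WM
            w = WM[i + 1, j] if i + 1 < j else INF
            if WM1[i, j] < w:
                w = WM1[i, j]
            for k in range(i + 1, j):
                if WM[i, k - 1] < INF and WM1[k, j] < INF:
                    e = WM[i, k - 1] + WM1[k, j]
                    if e < w:
                        w = e
            WM[i, j] = w
    F = np.zeros(n + 1, dtype=np.float64)  # F[j+1] = best energy of s[0..j]
    for j in range(0, n):
        best = F[j]
        for i in range(0, j):
            fi = F[i] + V[i, j]
            if fi < best:
                best = fi
        F[j + 1] = best
    energy = F[n]
    # traceback
    stack_i = np.empty(4 * n, dtype=np.int64)
    stack_j = np.empty(4 * n, dtype=np.int64)
    stack_m = np.empty(4 * n, dtype=np.int64)  # 0 ext, 1 V, 2 WM, 3 WM1
    top = 0
    stack_i[top] = 0
    stack_j[top] = n - 1
    stack_m[top] = 0
    top += 1
    eps = 1e-9
    while top > 0:
        top -= 1
        i = stack_i[top]
        j = stack_j[top]
        mode = stack_m[top]
        if mode == 0:
            # exterior region [i, j]; F-values refer to absolute prefix
            jj = j
            while jj >= i:
                done = False
                for ii in range(i, jj):
                    if abs(F[jj + 1] - (F[ii] + V[ii, jj])) < eps and V[ii, jj] < INF:
                        stack_i[top] = ii
                        stack_j[top] = jj
                        stack_m[top] = 1
                        top += 1
                        jj = ii - 1
                        done = True
                        break
                if not done:
                    jj -= 1
        elif mode == 1:
            partner[i] = j
            partner[j] = i
            pt = pair_type(s[i], s[j])
            v = V[i, j]
            if abs(v - e_hairpin(j - i - 1)) < eps:
                continue
            found = False
            for k in range(i + 1, j - 1):
                l1 = k - i - 1
                if l1 > MAXINTER:
                    break
                for l in range(j - 1, k + MINLOOP, -1):
                    l2 = j - l - 1
                    if l1 + l2 > MAXINTER:
                        break
                    if V[k, l] >= INF:
                        continue
                    pt2 = pair_type(s[k], s[l])
                    if pt2 < 0:
                        continue
                    if l1 == 0 and l2 == 0:
                        e = e_stack(pt, pt2) + V[k, l]
                    else:
                        e = e_interior(l1, l2) + V[k, l]
                    if abs(v - e) < eps:
                        stack_i[top] = k
                        stack_j[top] = l
                        stack_m[top] = 1
                        top += 1
                        found = True
                        break
                if found:
                    break
            if found:
                continue
            for k in range(i + 2, j - 1):
                if WM[i + 1, k - 1] < INF and WM1[k, j - 1] < INF:
                    e = ML_A + ML_B + WM[i + 1, k - 1] + WM1[k, j - 1]
                    if abs(v - e) < eps:
                        stack_i[top] = i + 1
                        stack_j[top] = k - 1
                        stack_m[top] = 2
                        top += 1
                        stack_i[top] = k
                        stack_j[top] = j - 1
                        stack_m[top] = 3
                        top += 1
                        break
        elif mode == 2:
            w = WM[i, j]
            if i + 1 < j and abs(w - WM[i + 1, j]) < eps:
                stack_i[top] = i + 1
                stack_j[top] = j
                stack_m[top] = 2
                top += 1
            elif abs(w - WM1[i, j]) < eps:
                stack_i[top] = i
                stack_j[top] = j
                stack_m[top] = 3
                top += 1
            else:
                for k in range(i + 1, j):
                    if WM[i, k - 1] < INF and WM1[k, j] < INF and \
                            abs(w - (WM[i, k - 1] + WM1[k, j])) < eps:
                        stack_i[top] = i
                        stack_j[top] = k - 1
                        stack_m[top] = 2
                        top += 1
                        stack_i[top] = k
                        stack_j[top] = j
                        stack_m[top] = 3
                        top += 1
                        break
        else:  # WM1: one branch starting at i, trailing unpaired
            w = WM1[i, j]
            jj = j
            while jj - 1 > i and abs(w - WM1[i, jj - 1]) < eps:
                jj -= 1
            stack_i[top] = i
            stack_j[top] = jj
            stack_m[top] = 1
            top += 1
    return energy, partner


@njit(cache=True)
def inside_kernel(s, RT, kappa):
    """McCaskill inside recursions in the rescaled domain.

    Returns (QB, QM, QM1, qe, qr). Every nucleotide carries a factor
    u = 1/kappa, so qe[n] = Z / kappa^n.
    """
    n = s.shape[0]
    u = 1.0 / kappa
    QB = np.zeros((n, n), dtype=np.float64)
    QM = np.zeros((n, n), dtype=np.float64)
    QM1 = np.zeros((n, n), dtype=np.float64)
    upow = np.empty(n + 2, dtype=np.float64)
    upow[0] = 1.0
    for k in range(1, n + 2):
        upow[k] = upow[k - 1] * u
    ebm = np.exp(-ML_B / RT)
    eml = np.exp(-(ML_A + ML_B) / RT)
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            pt = pair_type(s[i], s[j])
            if pt >= 0 and span > MINLOOP:
                q = np.exp(-e_hairpin(j - i - 1) / RT) * upow[j - i + 1]
                for k in range(i + 1, j - 1):
                    l1 = k - i - 1
                    if l1 > MAXINTER:
                        break
                    for l in range(j - 1, k + MINLOOP, -1):
                        l2 = j - l - 1
                        if l1 + l2 > MAXINTER:
                            break
                        if QB[k, l] == 0.0:
                            continue
                        pt2 = pair_type(s[k], s[l])
                        if l1 == 0 and l2 == 0:
                            e = e_stack(pt, pt2)
                        else:
                            e = e_interior(l1, l2)
                        q += np.exp(-e / RT) * QB[k, l] * upow[l1 + l2 + 2]
                for k in range(i + 2, j - 1):
                    if QM[i + 1, k - 1] > 0.0 and QM1[k, j - 1] > 0.0:
                        q += eml * u * u * QM[i + 1, k - 1] * QM1[k, j - 1]
                QB[i, j] = q
            # QM1: branch starts exactly at i, unpaired tail to j
            q1 = QB[i, j] * ebm
            if j - 1 > i:
                q1 += u * QM1[i, j - 1]
            QM1[i, j] = q1
            # QM: >=1 branch in [i, j]
            qm = QM1[i, j]
            if i + 1 < j:
                qm += u * QM[i + 1, j]
            for l in range(i + 1, j):
                if QB[i, l] > 0.0 and QM[l + 1, j] > 0.0:
                    qm += QB[i, l] * ebm * QM[l + 1, j]
            QM[i, j] = qm
    qe = np.empty(n + 1, dtype=np.float64)  # qe[k] = Z~ of prefix s[0..k-1]
    qe[0] = 1.0
    for j in range(0, n):
        acc = u * qe[j]
        for i in range(0, j + 1):
            if QB[i, j] > 0.0:
                acc += qe[i] * QB[i, j]
        qe[j + 1] = acc
    qr = np.empty(n + 2, dtype=np.float64)  # qr[i] = Z~ of suffix s[i..n-1]
    qr[n] = 1.0
    qr[n + 1] = 1.0
    for i in range(n - 1, -1, -1):
        acc = u * qr[i + 1]
        for j in range(i + 1, n):
            if QB[i, j] > 0.0:
                acc += QB[i, j] * qr[j + 1]
        qr[i] = acc
    return QB, QM, QM1, qe, qr


@njit(cache=True)
def outside_kernel(s, RT, kappa, QB, QM, qe, qr):
    """McCaskill outside pass: equilibrium base-pair probability matrix."""
    n = s.shape[0]
    u = 1.0 / kappa
    Z = qe[n]
    P = np.zeros((n, n), dtype=np.float64)
    X = np.zeros((n, n), dtype=np.float64)  # P / QB
    G = np.zeros((n, n), dtype=np.float64)  # G[p, j] = sum_q X[p,q] QM[j+1, q-1]
    Hs = np.zeros((n, n), dtype=np.float64)  # Hs[p, j] = sum_q X[p,q] u^(q-1-j)
    upow = np.empty(n + 2, dtype=np.float64)
    upow[0] = 1.0
    for k in range(1, n + 2):
        upow[k] = upow[k - 1] * u
    eml = np.exp(-(ML_A + 2.0 * ML_B) / RT)
    for span in range(n - 1, MINLOOP, -1):
        for i in range(0, n - span):
            j = i + span
            if QB[i, j] == 0.0:
                continue
            pt = pair_type(s[i], s[j])
            x = qe[i] * qr[j + 1] / Z
            # enclosed by an interior loop / stack of (p, q)
            for p in range(i - 1, -1, -1):
                l1 = i - p - 1
                if l1 > MAXINTER:
                    break
                for q in range(j + 1, n):
                    l2 = q - j - 1
                    if l1 + l2 > MAXINTER:
                        break
                    if X[p, q] == 0.0:
                        continue
                    pto = pair_type(s[p], s[q])
                    if pto < 0:
                        continue
                    if l1 == 0 and l2 == 0:
                        e = e_stack(pto, pt)
                    else:
                        e = e_interior(l1, l2)
                    x += np.exp(-e / RT) * upow[l1 + l2 + 2] * X[p, q]
            # branch of a multiloop closed by some (p, q)
            tml = 0.0
            for p in range(0, i):
                ta = upow[i - 1 - p] * G[p, j]
                tbc = 0.0
                if p + 1 <= i - 1:
                    qm = QM[p + 1, i - 1]
                    if qm > 0.0:
                        tbc = qm * (Hs[p, j] + G[p, j])
                tml += ta + tbc
            x += eml * u * u * tml
            P[i, j] = QB[i, j] * x
            P[j, i] = P[i, j]
            X[i, j] = x
        # expose this span's pairs to smaller spans
        for i in range(0, n - span):
            j = i + span
            if X[i, j] == 0.0:
                continue
            for jj in range(0, j - 1):
                if QM[jj + 1, j - 1] > 0.0:
                    G[i, jj] += X[i, j] * QM[jj + 1, j - 1]
            for jj in range(0, j):
                Hs[i, jj] += X[i, j] * upow[j - 1 - jj]
    return P
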