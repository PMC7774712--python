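"""Numba kernels: McCaskill inside/outside recursions and the duplex DP.

All arrays are plain float64/int8 numpy arrays prepared by the wrappers in
``partition.py`` and ``hybrid.py``; the kernels know nothing about the
energy model beyond the precomputed Boltzmann/energy tables they receive.

Notation (inside):
  qb[i,j]  partition function of [i..j] given that (i,j) pairs
  qm1[i,j] one multiloop branch starting at i, trailing bases unpaired
  qm[i,j]  at least one multiloop branch in [i..j]
  q[i,j]   unconstrained (exterior-weighted) partition function of [i..j]

Outside pass computes pair probabilities pb[i,j] in O(n^3) by processing
pairs in decreasing right-end order; multibranch contributions use the
column accumulators A (enclosing pair + qm to the left of the branch) and
Aun (enclosing pair + unpaired run to the left).
"""

import numpy as np
from numba import njit

NB_OPTS = dict(cache=True, fastmath=False)


@njit(**NB_OPTS)
def inside(W, PT, SW, EH, EB, EI, WCU, wa, wb, min_h, max_loop):
    n = W.shape[0]
    qb = np.zeros((n, n))
    qm1 = np.zeros((n, n))
    qm = np.zeros((n, n))
    q = np.zeros((n, n))
    for d in range(0, n):
        for i in range(0, n - d):
            j = i + d
            # --- qb ---
            if d > min_h and W[i, j] > 0.0:
                x = EH[d - 1]  # hairpin with u = j-i-1 unpaired
                kmax = j - 2
                for k in range(i + 1, kmax + 1):
                    u1 = k - i - 1
                    if u1 > max_loop:
                        break
                    lmin = k + min_h + 1
                    rem = max_loop - u1
                    if j - 1 - rem > lmin:
                        lmin = j - 1 - rem
                    for l in range(lmin, j):
                        if qb[k, l] > 0.0:
                            u2 = j - l - 1
                            if u1 == 0 and u2 == 0:
                                lw = SW[PT[i, j], PT[k, l]]
                            elif u1 == 0 or u2 == 0:
                                lw = EB[u1 + u2]
                            else:
                                lw = EI[u1 + u2]
                            x += lw * qb[k, l]
                # multibranch: >= 2 branches inside [i+1, j-1]
                ml = 0.0
                for h in range(i + 2, j - 1):
                    if qm[i + 1, h - 1] > 0.0 and qm1[h, j - 1] > 0.0:
                        ml += qm[i + 1, h - 1] * qm1[h, j - 1]
                x += wa * ml
                qb[i, j] = W[i, j] * x
            # --- qm1 ---
            s = 0.0
            for l in range(i + min_h + 1, j + 1):
                if qb[i, l] > 0.0:
                    s += qb[i, l] * WCU[j - l]
            qm1[i, j] = wb * s
            # --- qm ---
            s = 0.0
            for k in range(i, j + 1):
                if qm1[k, j] > 0.0:
                    s += WCU[k - i] * qm1[k, j]
                    if k > i:
                        s += qm[i, k - 1] * qm1[k, j]
            qm[i, j] = s
            # --- exterior q ---
            acc = 1.0 if d == 0 else q[i, j - 1]
            for k in range(i, j - min_h):
                if qb[k, j] > 0.0:
                    left = 1.0 if k == i else q[i, k - 1]
                    acc += left * qb[k, j]
            q[i, j] = acc
    return q, qb, qm1, qm


@njit(**NB_OPTS)
def outside(q, qb, qm, W, PT, SW, EB, EI, WCU, wa, wb, min_h, max_loop):
    n = q.shape[0]
    Z = q[0, n - 1]
    pb = np.zeros((n, n))
    OW = np.zeros((n, n))       # pb/qb * W, for enclosing-pair reuse
    A = np.zeros((n, n))        # A[i,l]: sum_k OW[k,l]*qm[k+1,i-1]
    Aun = np.zeros((n, n))      # Aun[i,l]: sum_k OW[k,l]*WCU[i-k-1]
    for j in range(n - 1, min_h, -1):
        for i in range(0, j - min_h):
            if qb[i, j] <= 0.0:
                continue
            # exterior
            left = 1.0 if i == 0 else q[0, i - 1]
            right = 1.0 if j == n - 1 else q[j + 1, n - 1]
            tot = left * right / Z * qb[i, j]
            # enclosed in an interior/bulge/stack loop of (k,l)
            acc = 0.0
            for k in range(max(0, i - max_loop - 1), i):
                u1 = i - k - 1
                lmax = j + 1 + (max_loop - u1)
                if lmax > n - 1:
                    lmax = n - 1
                for l in range(j + 1, lmax + 1):
                    if OW[k, l] > 0.0:
                        u2 = l - j - 1
                        if u1 == 0 and u2 == 0:
                            lw = SW[PT[k, l], PT[i, j]]
                        elif u1 == 0 or u2 == 0:
                            lw = EB[u1 + u2]
                        else:
                            lw = EI[u1 + u2]
                        acc += OW[k, l] * lw
            tot += acc * qb[i, j]
            # branch of a multiloop closed by some (k,l), l > j
            t = 0.0
            for l in range(j + 1, n):
                a = A[i, l]
                au = Aun[i, l]
                if a == 0.0 and au == 0.0:
                    continue
                qmr = qm[j + 1, l - 1] if l - 1 >= j + 1 else 0.0
                t += a * (WCU[l - j - 1] + qmr) + au * qmr
            tot += wa * wb * qb[i, j] * t
            pb[i, j] = tot
            OW[i, j] = tot / qb[i, j] * W[i, j]
        # column j of OW is now complete: fill accumulators for later pairs
        for i2 in range(1, j):
            # A[i2, j] needs OW[k, j] for k < i2
            s = 0.0
            su = 0.0
            for k in range(0, i2):
                ow = OW[k, j]
                if ow > 0.0:
                    if i2 - 1 >= k + 1:
                        s += ow * qm[k + 1, i2 - 1]
                    su += ow * WCU[i2 - k - 1]
            A[i2, j] = s
            Aun[i2, j] = su
    return pb


@njit(**NB_OPTS)
def duplex_mfe(m, t, PT4, SE, BE, IE, init, max_bulge):
    """Minimum free energy of an antiparallel intermolecular duplex.

    ``m`` (query, 5'->3') and ``t`` (target, 5'->3') as base indices.
    Consecutive pairs (k,l) -> (i,j) satisfy k < i and l > j; zero gaps
    stack, otherwise bulge/internal penalties apply (per-side cap
    ``max_bulge``).  Returns (found, energy): energy of the best chain
    including the initiation term, or (False, 0.0) when no pair is legal.
    """
    M = len(m)
    N = len(t)
    NEG = 1e30
    E = np.full((M, N), NEG)
    best = NEG
    found = False
    for i in range(M):
        for j in range(N - 1, -1, -1):
            pt = PT4[m[i], t[j]]
            if pt < 0:
                continue
            found = True
            e = init  # (i,j) opens the duplex
            for k in range(max(0, i - max_bulge - 1), i):
                u1 = i - k - 1
                lmax = j + 1 + max_bulge
                if lmax > N - 1:
                    lmax = N - 1
                for l in range(j + 1, lmax + 1):
                    if E[k, l] < NEG:
                        u2 = l - j - 1
                        if u1 == 0 and u2 == 0:
                            cost = SE[PT4[m[k], t[l]], pt]
                        elif u1 == 0 or u2 == 0:
                            cost = BE[u1 + u2]
                        else:
                            cost = IE[u1 + u2]
                        cand = E[k, l] + cost
                        if cand < e:
                            e = cand
            E[i, j] = e
            if e < best:
                best = e
    if not found:
        return False, 0.0
    return True, best


@njit(**NB_OPTS)
def pair_distance_sq(p_wt, p_alt):
    """Upper-triangle squared-difference matrix between two bppms."""
    n = p_wt.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            x = p_wt[i, j] - p_alt[i, j]
            d[i, j] = x * x
    return d
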