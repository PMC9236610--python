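"""Numba kernels for the partition function, MFE and stochastic traceback.

All recursions work in log-weight space (log of Boltzmann-weighted sums),
which keeps 200+ nt sequences free of overflow without rescaling tricks.
Positions are 0-based inside the kernels.  The decomposition mirrors the
loop model of :mod:`psifold.energy` exactly:

``B(i,j)``   structures on [i,j] with (i,j) paired;
``M1(i,j)``  one multiloop branch starting exactly at i, plus 3' unpaired;
``M(i,j)``   at least one multiloop branch (per-branch and per-unpaired
             multiloop terms included);
``Qpre/Qsuf`` exterior-loop prefix/suffix partition functions.

Every structure's weight exp(-E/RT) is counted exactly once; the
enumeration oracle in the test-suite pins this down to 1e-9 relative.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e30  # log-space "zero"
EPS = 1e-9     # energy tie tolerance in the MFE recursions


@njit(cache=True, inline="always")
def _lse(a, b):
    if a <= NEG / 2:
        return b
    if b <= NEG / 2:
        return a
    if a > b:
        return a + np.log1p(np.exp(b - a))
    return b + np.log1p(np.exp(a - b))


@njit(cache=True)
def inside(seq, ptype, stack, hairpin, internal, au,
           ml_a, ml_b, ml_c, dms, RT, max_int):
    n = seq.shape[0]
    B = np.full((n, n), NEG)
    M = np.full((n, n), NEG)
    M1 = np.full((n, n), NEG)
    for d in range(4, n):
        for i in range(0, n - d):
            j = i + d
            t = ptype[seq[i], seq[j]]
            if t >= 0:
                # hairpin
                acc = -(hairpin[j - i - 1] + au[t]) / RT
                # stack on (i+1, j-1)
                if B[i + 1, j - 1] > NEG / 2:
                    t2 = ptype[seq[i + 1], seq[j - 1]]
                    acc = _lse(acc, B[i + 1, j - 1] - stack[t, t2] / RT)
                # internal / bulge loops up to max_int unpaired
                for k in range(i + 1, min(i + 2 + max_int, j - 4)):
                    lmin = max(k + 4, j - 1 - (max_int - (k - i - 1)))
                    for l in range(lmin, j):
                        if k == i + 1 and l == j - 1:
                            continue
                        if B[k, l] > NEG / 2:
                            L = (k - i - 1) + (j - l - 1)
                            t3 = ptype[seq[k], seq[l]]
                            acc = _lse(acc, B[k, l]
                                       - (internal[L] + au[t] + au[t3]) / RT)
                # multiloop: closing (i,j), >= 2 interior branches
                mlw = -(ml_a + ml_b + au[t]) / RT
                for k in range(i + 6, j - 4):
                    if M[i + 1, k - 1] > NEG / 2 and M1[k, j - 1] > NEG / 2:
                        acc = _lse(acc, mlw + M[i + 1, k - 1] + M1[k, j - 1])
                B[i, j] = acc - (dms[i] + dms[j]) / RT
            # M1: branch starts exactly at i
            acc1 = NEG
            if M1[i, j - 1] > NEG / 2:
                acc1 = M1[i, j - 1] - ml_c / RT
            if B[i, j] > NEG / 2:
                tb = ptype[seq[i], seq[j]]
                acc1 = _lse(acc1, B[i, j] - (au[tb] + ml_b) / RT)
            M1[i, j] = acc1
            # M: >= 1 branch, decomposition by last branch start k
            accm = NEG
            for k in range(i, j - 3):
                if M1[k, j] > NEG / 2:
                    accm = _lse(accm, -ml_c * (k - i) / RT + M1[k, j])
                    if k > i and M[i, k - 1] > NEG / 2:
                        accm = _lse(accm, M[i, k - 1] + M1[k, j])
            M[i, j] = accm
    # exterior prefix / suffix
    Qpre = np.zeros(n + 1)
    for m in range(1, n + 1):
        acc = Qpre[m - 1]
        j = m - 1
        for i in range(0, j - 3):
            if B[i, j] > NEG / 2:
                t = ptype[seq[i], seq[j]]
                acc = _lse(acc, Qpre[i] + B[i, j] - au[t] / RT)
        Qpre[m] = acc
    Qsuf = np.zeros(n + 1)
    for m in range(n - 1, -1, -1):
        acc = Qsuf[m + 1]
        for j in range(m + 4, n):
            if B[m, j] > NEG / 2:
                t = ptype[seq[m], seq[j]]
                acc = _lse(acc, B[m, j] - au[t] / RT + Qsuf[j + 1])
        Qsuf[m] = acc
    return B, M, M1, Qpre, Qsuf


@njit(cache=True)
def outside(seq, ptype, stack, hairpin, internal, au,
            ml_a, ml_b, ml_c, dms, RT, max_int, B, M, M1, Qpre, Qsuf):
    n = seq.shape[0]
    OB = np.full((n, n), NEG)
    OM = np.full((n, n), NEG)
    OM1 = np.full((n, n), NEG)
    # exterior-loop contexts
    for i in range(n):
        for j in range(i + 4, n):
            if B[i, j] > NEG / 2:
                t = ptype[seq[i], seq[j]]
                OB[i, j] = Qpre[i] + Qsuf[j + 1] - au[t] / RT
    for d in range(n - 1, 3, -1):
        for i in range(0, n - d):
            j = i + d
            # ---- OM(i,j) pushes (QM decomposition by last branch start)
            if OM[i, j] > NEG / 2:
                for k in range(i, j - 3):
                    if M1[k, j] > NEG / 2:
                        OM1[k, j] = _lse(OM1[k, j],
                                         OM[i, j] - ml_c * (k - i) / RT)
                        if k > i and M[i, k - 1] > NEG / 2:
                            OM1[k, j] = _lse(OM1[k, j], OM[i, j] + M[i, k - 1])
                            OM[i, k - 1] = _lse(OM[i, k - 1],
                                                OM[i, j] + M1[k, j])
            # ---- OM1(i,j) pushes (QM1 = B(i,l) + 3' unpaired)
            if OM1[i, j] > NEG / 2:
                if M1[i, j - 1] > NEG / 2:
                    OM1[i, j - 1] = _lse(OM1[i, j - 1], OM1[i, j] - ml_c / RT)
                if B[i, j] > NEG / 2:
                    t = ptype[seq[i], seq[j]]
                    OB[i, j] = _lse(OB[i, j],
                                    OM1[i, j] - (au[t] + ml_b) / RT)
            # ---- OB(i,j) pushes into its loop children
            if OB[i, j] > NEG / 2 and B[i, j] > NEG / 2:
                t = ptype[seq[i], seq[j]]
                base = OB[i, j] - (dms[i] + dms[j]) / RT
                if B[i + 1, j - 1] > NEG / 2:
                    t2 = ptype[seq[i + 1], seq[j - 1]]
                    OB[i + 1, j - 1] = _lse(OB[i + 1, j - 1],
                                            base - stack[t, t2] / RT)
                for k in range(i + 1, min(i + 2 + max_int, j - 4)):
                    lmin = max(k + 4, j - 1 - (max_int - (k - i - 1)))
                    for l in range(lmin, j):
                        if k == i + 1 and l == j - 1:
                            continue
                        if B[k, l] > NEG / 2:
                            L = (k - i - 1) + (j - l - 1)
                            t3 = ptype[seq[k], seq[l]]
                            OB[k, l] = _lse(
                                OB[k, l],
                                base - (internal[L] + au[t] + au[t3]) / RT)
                mlw = base - (ml_a + ml_b + au[t]) / RT
                for k in range(i + 6, j - 4):
                    if M[i + 1, k - 1] > NEG / 2 and M1[k, j - 1] > NEG / 2:
                        OM[i + 1, k - 1] = _lse(OM[i + 1, k - 1],
                                                mlw + M1[k, j - 1])
                        OM1[k, j - 1] = _lse(OM1[k, j - 1],
                                             mlw + M[i + 1, k - 1])
    return OB


@njit(cache=True)
def pair_probabilities(B, OB, logZ):
    n = B.shape[0]
    P = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 4, n):
            if B[i, j] > NEG / 2 and OB[i, j] > NEG / 2:
                p = np.exp(B[i, j] + OB[i, j] - logZ)
                if p > 1.0:
                    p = 1.0
                P[i, j] = p
                P[j, i] = p
    return P


# ---------------------------------------------------------------------------
# MFE with (energy, pair-count) lexicographic optimization
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _better(e1, n1, e2, n2):
    """True when (e1, n1) improves on incumbent (e2, n2)."""
    if e1 < e2 - EPS:
        return True
    if e1 <= e2 + EPS and n1 < n2:
        return True
    return False


@njit(cache=True)
def mfe_tables(seq, ptype, stack, hairpin, internal, au,
               ml_a, ml_b, ml_c, dms, RT, max_int):
    n = seq.shape[0]
    INF = 1.0e30
    VB = np.full((n, n), INF)
    VM = np.full((n, n), INF)
    VM1 = np.full((n, n), INF)
    NB = np.zeros((n, n), dtype=np.int32)
    NM = np.zeros((n, n), dtype=np.int32)
    NM1 = np.zeros((n, n), dtype=np.int32)
    for d in range(4, n):
        for i in range(0, n - d):
            j = i + d
            t = ptype[seq[i], seq[j]]
            if t >= 0:
                be = hairpin[j - i - 1] + au[t]
                bn = 0
                if VB[i + 1, j - 1] < INF / 2:
                    t2 = ptype[seq[i + 1], seq[j - 1]]
                    e = VB[i + 1, j - 1] + stack[t, t2]
                    if _better(e, NB[i + 1, j - 1], be, bn):
                        be, bn = e, NB[i + 1, j - 1]
                for k in range(i + 1, min(i + 2 + max_int, j - 4)):
                    lmin = max(k + 4, j - 1 - (max_int - (k - i - 1)))
                    for l in range(lmin, j):
                        if k == i + 1 and l == j - 1:
                            continue
                        if VB[k, l] < INF / 2:
                            L = (k - i - 1) + (j - l - 1)
                            t3 = ptype[seq[k], seq[l]]
                            e = VB[k, l] + internal[L] + au[t] + au[t3]
                            if _better(e, NB[k, l], be, bn):
                                be, bn = e, NB[k, l]
                for k in range(i + 6, j - 4):
                    if VM[i + 1, k - 1] < INF / 2 and VM1[k, j - 1] < INF / 2:
                        e = (VM[i + 1, k - 1] + VM1[k, j - 1]
                             + ml_a + ml_b + au[t])
                        cn = NM[i + 1, k - 1] + NM1[k, j - 1]
                        if _better(e, cn, be, bn):
                            be, bn = e, cn
                VB[i, j] = be + dms[i] + dms[j]
                NB[i, j] = bn + 1
            # M1
            be1, bn1 = INF, 0
            if VM1[i, j - 1] < INF / 2:
                be1, bn1 = VM1[i, j - 1] + ml_c, NM1[i, j - 1]
            if VB[i, j] < INF / 2:
                tb = ptype[seq[i], seq[j]]
                e = VB[i, j] + au[tb] + ml_b
                if _better(e, NB[i, j], be1, bn1):
                    be1, bn1 = e, NB[i, j]
            VM1[i, j], NM1[i, j] = be1, bn1
            # M
            bem, bnm = INF, 0
            for k in range(i, j - 3):
                if VM1[k, j] < INF / 2:
                    e = ml_c * (k - i) + VM1[k, j]
                    if _better(e, NM1[k, j], bem, bnm):
                        bem, bnm = e, NM1[k, j]
                    if k > i and VM[i, k - 1] < INF / 2:
                        e = VM[i, k - 1] + VM1[k, j]
                        cn = NM[i, k - 1] + NM1[k, j]
                        if _better(e, cn, bem, bnm):
                            bem, bnm = e, cn
            VM[i, j], NM[i, j] = bem, bnm
    W = np.zeros(n + 1)
    NW = np.zeros(n + 1, dtype=np.int32)
    for m in range(1, n + 1):
        be, bn = W[m - 1], NW[m - 1]
        j = m - 1
        for i in range(0, j - 3):
            if VB[i, j] < INF / 2:
                t = ptype[seq[i], seq[j]]
                e = W[i] + VB[i, j] + au[t]
                cn = NW[i] + NB[i, j]
                if _better(e, cn, be, bn):
                    be, bn = e, cn
        W[m], NW[m] = be, bn
    return VB, VM, VM1, NB, NM, NM1, W, NW


@njit(cache=True)
def mfe_traceback(seq, ptype, stack, hairpin, internal, au,
                  ml_a, ml_b, ml_c, dms, RT, max_int,
                  VB, VM, VM1, NB, NM, NM1, W, NW):
    n = seq.shape[0]
    INF = 1.0e30
    pt = np.zeros(n, dtype=np.int32) - 1
    # stack of tasks: kind 0=W prefix [0..j], 1=B(i,j), 2=M(i,j), 3=M1(i,j)
    cap = 4 * n + 8
    tk = np.zeros(cap, dtype=np.int8)
    ti = np.zeros(cap, dtype=np.int32)
    tj = np.zeros(cap, dtype=np.int32)
    top = 0
    tk[top], ti[top], tj[top] = 0, 0, n
    top += 1
    while top > 0:
        top -= 1
        kind, a, b = tk[top], ti[top], tj[top]
        if kind == 0:  # exterior prefix of length b
            m = b
            while m > 0:
                j = m - 1
                if abs(W[m] - W[m - 1]) <= EPS and NW[m] == NW[m - 1]:
                    m -= 1
                    continue
                done = False
                for i in range(0, j - 3):
                    if VB[i, j] < INF / 2:
                        t = ptype[seq[i], seq[j]]
                        e = W[i] + VB[i, j] + au[t]
                        if (abs(e - W[m]) <= EPS
                                and NW[i] + NB[i, j] == NW[m]):
                            pt[i], pt[j] = j, i
                            tk[top], ti[top], tj[top] = 1, i, j
                            top += 1
                            m = i
                            done = True
                            break
                if not done:
                    m -= 1
        elif kind == 1:  # B(i,j)
            i, j = a, b
            t = ptype[seq[i], seq[j]]
            target = VB[i, j] - dms[i] - dms[j]
            cnt = NB[i, j] - 1
            if (abs(hairpin[j - i - 1] + au[t] - target) <= EPS
                    and cnt == 0):
                continue
            matched = False
            if VB[i + 1, j - 1] < INF / 2:
                t2 = ptype[seq[i + 1], seq[j - 1]]
                e = VB[i + 1, j - 1] + stack[t, t2]
                if abs(e - target) <= EPS and NB[i + 1, j - 1] == cnt:
                    pt[i + 1], pt[j - 1] = j - 1, i + 1
                    tk[top], ti[top], tj[top] = 1, i + 1, j - 1
                    top += 1
                    matched = True
            if not matched:
                for k in range(i + 1, min(i + 2 + max_int, j - 4)):
                    if matched:
                        break
                    lmin = max(k + 4, j - 1 - (max_int - (k - i - 1)))
                    for l in range(lmin, j):
                        if k == i + 1 and l == j - 1:
                            continue
                        if VB[k, l] < INF / 2:
                            L = (k - i - 1) + (j - l - 1)
                            t3 = ptype[seq[k], seq[l]]
                            e = VB[k, l] + internal[L] + au[t] + au[t3]
                            if abs(e - target) <= EPS and NB[k, l] == cnt:
                                pt[k], pt[l] = l, k
                                tk[top], ti[top], tj[top] = 1, k, l
                                top += 1
                                matched = True
                                break
            if not matched:
                for k in range(i + 6, j - 4):
                    if VM[i + 1, k - 1] < INF / 2 and VM1[k, j - 1] < INF / 2:
                        e = (VM[i + 1, k - 1] + VM1[k, j - 1]
                             + ml_a + ml_b + au[t])
                        cn = NM[i + 1, k - 1] + NM1[k, j - 1]
                        if abs(e - target) <= EPS and cn == cnt:
                            tk[top], ti[top], tj[top] = 2, i + 1, k - 1
                            top += 1
                            tk[top], ti[top], tj[top] = 3, k, j - 1
                            top += 1
                            matched = True
                            break
        elif kind == 2:  # M(i,j)
            i, j = a, b
            for k in range(i, j - 3):
                if VM1[k, j] < INF / 2:
                    e = ml_c * (k - i) + VM1[k, j]
                    if abs(e - VM[i, j]) <= EPS and NM1[k, j] == NM[i, j]:
                        tk[top], ti[top], tj[top] = 3, k, j
                        top += 1
                        break
                    if k > i and VM[i, k - 1] < INF / 2:
                        e = VM[i, k - 1] + VM1[k, j]
                        cn = NM[i, k - 1] + NM1[k, j]
                        if abs(e - VM[i, j]) <= EPS and cn == NM[i, j]:
                            tk[top], ti[top], tj[top] = 2, i, k - 1
                            top += 1
                            tk[top], ti[top], tj[top] = 3, k, j
                            top += 1
                            break
        else:  # M1(i,j): branch (i,l) + 3' unpaired
            i, j = a, b
            jj = j
            while jj >= i + 4:
                tb = ptype[seq[i], seq[jj]]
                hit = False
                if VB[i, jj] < INF / 2:
                    e = VB[i, jj] + au[tb] + ml_b + ml_c * (j - jj)
                    if abs(e - VM1[i, j]) <= EPS and NB[i, jj] == NM1[i, j]:
                        pt[i], pt[jj] = jj, i
                        tk[top], ti[top], tj[top] = 1, i, jj
                        top += 1
                        hit = True
                if hit:
                    break
                jj -= 1
    return pt


# ---------------------------------------------------------------------------
# Stochastic traceback
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _xorshift(state):
    s = state
    s ^= s >> np.uint64(12)
    s ^= (s << np.uint64(25)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    s ^= s >> np.uint64(27)
    val = (s * np.uint64(2685821657736338717)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return s, (np.float64(val >> np.uint64(11)) / 9007199254740992.0)


@njit(cache=True)
def sample_tracebacks(seq, ptype, stack, hairpin, internal, au,
                      ml_a, ml_b, ml_c, dms, RT, max_int,
                      B, M, M1, Qpre, Qsuf, n_samples, seed):
    n = seq.shape[0]
    out = np.zeros((n_samples, n), dtype=np.int32) - 1
    state = np.uint64(seed * np.uint64(6364136223846793005)
                      + np.uint64(1442695040888963407))
    if state == np.uint64(0):
        state = np.uint64(0x9E3779B97F4A7C15)
    # scratch buffers for option weights
    cap = n + (max_int + 2) * (max_int + 2) + 16
    wbuf = np.zeros(cap)
    kbuf = np.zeros(cap, dtype=np.int32)
    lbuf = np.zeros(cap, dtype=np.int32)
    cbuf = np.zeros(cap, dtype=np.int8)
    scap = 4 * n + 8
    tk = np.zeros(scap, dtype=np.int8)
    ti = np.zeros(scap, dtype=np.int32)
    tj = np.zeros(scap, dtype=np.int32)

    for s_idx in range(n_samples):
        pt = out[s_idx]
        top = 0
        tk[top], ti[top], tj[top] = 0, 0, n
        top += 1
        while top > 0:
            top -= 1
            kind, a, b = tk[top], ti[top], tj[top]
            if kind == 0:  # exterior prefix of length b
                m = b
                while m > 0:
                    j = m - 1
                    nopt = 0
                    wbuf[nopt] = Qpre[m - 1]
                    cbuf[nopt] = 0
                    nopt += 1
                    for i in range(0, j - 3):
                        if B[i, j] > NEG / 2:
                            t = ptype[seq[i], seq[j]]
                            wbuf[nopt] = Qpre[i] + B[i, j] - au[t] / RT
                            cbuf[nopt] = 1
                            kbuf[nopt] = i
                            nopt += 1
                    sel = _pick(wbuf, nopt, state)
                    state, sel = sel[0], sel[1]
                    if cbuf[sel] == 0:
                        m -= 1
                    else:
                        i = kbuf[sel]
                        pt[i], pt[j] = j, i
                        tk[top], ti[top], tj[top] = 1, i, j
                        top += 1
                        m = i
            elif kind == 1:  # B(i,j)
                i, j = a, b
                t = ptype[seq[i], seq[j]]
                nopt = 0
                wbuf[nopt] = -(hairpin[j - i - 1] + au[t]) / RT
                cbuf[nopt] = 0
                nopt += 1
                if B[i + 1, j - 1] > NEG / 2:
                    t2 = ptype[seq[i + 1], seq[j - 1]]
                    wbuf[nopt] = B[i + 1, j - 1] - stack[t, t2] / RT
                    cbuf[nopt] = 1
                    kbuf[nopt], lbuf[nopt] = i + 1, j - 1
                    nopt += 1
                for k in range(i + 1, min(i + 2 + max_int, j - 4)):
                    lmin = max(k + 4, j - 1 - (max_int - (k - i - 1)))
                    for l in range(lmin, j):
                        if k == i + 1 and l == j - 1:
                            continue
                        if B[k, l] > NEG / 2:
                            L = (k - i - 1) + (j - l - 1)
                            t3 = ptype[seq[k], seq[l]]
                            wbuf[nopt] = (B[k, l]
                                          - (internal[L] + au[t] + au[t3]) / RT)
                            cbuf[nopt] = 1
                            kbuf[nopt], lbuf[nopt] = k, l
                            nopt += 1
                mlw = -(ml_a + ml_b + au[t]) / RT
                for k in range(i + 6, j - 4):
                    if M[i + 1, k - 1] > NEG / 2 and M1[k, j - 1] > NEG / 2:
                        wbuf[nopt] = mlw + M[i + 1, k - 1] + M1[k, j - 1]
                        cbuf[nopt] = 2
                        kbuf[nopt] = k
                        nopt += 1
                res = _pick(wbuf, nopt, state)
                state, sel = res[0], res[1]
                if cbuf[sel] == 1:
                    k, l = kbuf[sel], lbuf[sel]
                    pt[k], pt[l] = l, k
                    tk[top], ti[top], tj[top] = 1, k, l
                    top += 1
                elif cbuf[sel] == 2:
                    k = kbuf[sel]
                    tk[top], ti[top], tj[top] = 2, i + 1, k - 1
                    top += 1
                    tk[top], ti[top], tj[top] = 3, k, j - 1
                    top += 1
            elif kind == 2:  # M(i,j)
                i, j = a, b
                nopt = 0
                for k in range(i, j - 3):
                    if M1[k, j] > NEG / 2:
                        wbuf[nopt] = -ml_c * (k - i) / RT + M1[k, j]
                        cbuf[nopt] = 0
                        kbuf[nopt] = k
                        nopt += 1
                        if k > i and M[i, k - 1] > NEG / 2:
                            wbuf[nopt] = M[i, k - 1] + M1[k, j]
                            cbuf[nopt] = 1
                            kbuf[nopt] = k
                            nopt += 1
                res = _pick(wbuf, nopt, state)
                state, sel = res[0], res[1]
                k = kbuf[sel]
                tk[top], ti[top], tj[top] = 3, k, j
                top += 1
                if cbuf[sel] == 1:
                    tk[top], ti[top], tj[top] = 2, i, k - 1
                    top += 1
            else:  # M1(i,j)
                i, j = a, b
                nopt = 0
                for l in range(i + 4, j + 1):
                    if B[i, l] > NEG / 2:
                        tb = ptype[seq[i], seq[l]]
                        wbuf[nopt] = (B[i, l]
                                      - (au[tb] + ml_b + ml_c * (j - l)) / RT)
                        kbuf[nopt] = l
                        nopt += 1
                res = _pick(wbuf, nopt, state)
                state, sel = res[0], res[1]
                l = kbuf[sel]
                pt[i], pt[l] = l, i
                tk[top], ti[top], tj[top] = 1, i, l
                top += 1
    return out


@njit(cache=True)
def _pick(wbuf, nopt, state):
    """Sample an index proportionally to exp(wbuf[:nopt]) (log weights)."""
    mx = NEG
    for q in range(nopt):
        if wbuf[q] > mx:
            mx = wbuf[q]
    tot = 0.0
    for q in range(nopt):
        tot += np.exp(wbuf[q] - mx)
    state, u = _xorshift(state)
    thresh = u * tot
    acc = 0.0
    sel = nopt - 1
    for q in range(nopt):
        acc += np.exp(wbuf[q] - mx)
        if acc >= thresh:
            sel = q
            break
    return state, sel
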