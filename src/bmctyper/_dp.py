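"""Forward and Viterbi dynamic programming over the search-configured profile.

The search model is a multihit local Plan7-style topology:

* flanking states N (before), C (after) and J (between domains) that emit
  query residues with background probability on their self-loops; loop and
  move probabilities are all 0.5 (``S->N->B (core) E->{J|C}``, ``J->B``,
  ``C->T``);
* uniform local entry ``B->M_k`` with probability 1/L for every match state;
* a per-match-state local exit ``M_k->E`` with probability epsilon
  (default 0.05) folded multiplicatively into the core transitions, except
  the last match state which exits with probability 1;
* delete states D_2..D_L reachable through ``M->D``/``D->D``; ``D_L->E``
  with probability 1; insert states I_1..I_{L-1}.

All recurrences run in natural-log space.  Because the flanking states emit
with the same background used by the null model, flank emissions cancel in
the reported log-odds bit score.

The kernels are JIT-compiled with numba when available; the pure-Python
definitions are the reference semantics either way.
"""

from __future__ import annotations

import math

import numpy as np

NEG_INF = float("-inf")

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def _lse(a: float, b: float) -> float:
    if a == NEG_INF:
        return b
    if b == NEG_INF:
        return a
    if a > b:
        return a + math.log1p(math.exp(b - a))
    return b + math.log1p(math.exp(a - b))


@njit(cache=True)
def forward_logprob(seqi, lem, lei, lbg, lmm, lmi, lmd, lme,
                    lim, lii, ldm, ldd, lbm, lmove):
    """log P(sequence | search-configured profile), forward algorithm."""
    n = seqi.shape[0]
    L = lem.shape[0]
    Mp = np.full(L, NEG_INF)
    Ip = np.full(L, NEG_INF)
    Dp = np.full(L, NEG_INF)
    Mc = np.empty(L)
    Ic = np.empty(L)
    Dc = np.empty(L)
    N = 0.0
    B = lmove  # N -> B before any residue
    J = NEG_INF
    C = NEG_INF
    for i in range(n):
        x = seqi[i]
        bgx = lbg[x]
        for j in range(L):
            acc = B + lbm
            if j > 0:
                acc = _lse(acc, Mp[j - 1] + lmm[j - 1])
                acc = _lse(acc, Ip[j - 1] + lim[j - 1])
                acc = _lse(acc, Dp[j - 1] + ldm[j - 1])
            Mc[j] = lem[j, x] + acc
        for j in range(L):
            if j < L - 1:
                Ic[j] = lei[x] + _lse(Mp[j] + lmi[j], Ip[j] + lii[j])
            else:
                Ic[j] = NEG_INF
        Dc[0] = NEG_INF
        for j in range(1, L):
            Dc[j] = _lse(Mc[j - 1] + lmd[j - 1], Dc[j - 1] + ldd[j - 1])
        E = NEG_INF
        for j in range(L):
            E = _lse(E, Mc[j] + lme[j])
        if L > 1:
            E = _lse(E, Dc[L - 1])  # D_L -> E, probability 1
        J = _lse(J + lmove + bgx, E + lmove)
        N = N + lmove + bgx
        B = _lse(N + lmove, J + lmove)
        C = _lse(C + lmove + bgx, E + lmove)
        Mp, Mc = Mc, Mp
        Ip, Ic = Ic, Ip
        Dp, Dc = Dc, Dp
    return C + lmove


@njit(cache=True)
def viterbi_matrices(seqi, lem, lei, lbg, lmm, lmi, lmd, lme,
                     lim, lii, ldm, ldd, lbm, lmove):
    """Viterbi fill; returns full matrices for traceback plus the score.

    Row i of each matrix corresponds to having consumed i residues
    (row 0 = none).
    """
    n = seqi.shape[0]
    L = lem.shape[0]
    VM = np.full((n + 1, L), NEG_INF)
    VI = np.full((n + 1, L), NEG_INF)
    VD = np.full((n + 1, L), NEG_INF)
    VN = np.full(n + 1, NEG_INF)
    VB = np.full(n + 1, NEG_INF)
    VJ = np.full(n + 1, NEG_INF)
    VC = np.full(n + 1, NEG_INF)
    VE = np.full(n + 1, NEG_INF)
    VN[0] = 0.0
    VB[0] = lmove
    for i in range(1, n + 1):
        x = seqi[i - 1]
        bgx = lbg[x]
        for j in range(L):
            best = VB[i - 1] + lbm
            if j > 0:
                c = VM[i - 1, j - 1] + lmm[j - 1]
                if c > best:
                    best = c
                c = VI[i - 1, j - 1] + lim[j - 1]
                if c > best:
                    best = c
                c = VD[i - 1, j - 1] + ldm[j - 1]
                if c > best:
                    best = c
            VM[i, j] = lem[j, x] + best
        for j in range(L - 1):
            a = VM[i - 1, j] + lmi[j]
            b = VI[i - 1, j] + lii[j]
            VI[i, j] = lei[x] + (a if a > b else b)
        for j in range(1, L):
            a = VM[i, j - 1] + lmd[j - 1]
            b = VD[i, j - 1] + ldd[j - 1]
            VD[i, j] = a if a > b else b
        e = NEG_INF
        for j in range(L):
            c = VM[i, j] + lme[j]
            if c > e:
                e = c
        if L > 1 and VD[i, L - 1] > e:
            e = VD[i, L - 1]
        VE[i] = e
        a = VJ[i - 1] + lmove + bgx
        b = VE[i] + lmove
        VJ[i] = a if a > b else b
        VN[i] = VN[i - 1] + lmove + bgx
        a = VN[i] + lmove
        b = VJ[i] + lmove
        VB[i] = a if a > b else b
        a = VC[i - 1] + lmove + bgx
        b = VE[i] + lmove
        VC[i] = a if a > b else b
    return VM, VI, VD, VN, VB, VJ, VC, VE, VC[n] + lmove
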