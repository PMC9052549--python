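"""Independent reference implementations used only by the tests.

These deliberately avoid the package's dynamic-programming and similarity
code paths: the forward probability is obtained by exhaustively enumerating
every state path of the configured search model, and the order component of
the locus similarity by a literal double loop over all offsets and both
orientations.
"""

from __future__ import annotations

import math

from bmctyper.alphabet import encode


def enumerate_forward_logprob(profile, seq: str, epsilon: float = 0.05) -> float:
    """Sum of path probabilities over every complete state path.

    Mirrors the configured topology state by state: N/C/J flanks with 0.5
    loop/move emitting background, uniform B->M entry, per-state exit, the
    D_L->E probability-1 exit.  Exponential in sequence length; only usable
    on tiny profiles/queries.
    """
    (lem, lei, lbg, lmm, lmi, lmd, lme,
     lim, lii, ldm, ldd, lbm, lmove) = profile.score_tables(epsilon)
    seqi = encode(seq)
    n, L = len(seqi), profile.length
    total = 0.0

    def rec(state, j, pos, logp):
        nonlocal total
        if state == "N":
            if pos < n:
                rec("N", -1, pos + 1, logp + lmove + lbg[seqi[pos]])
            rec("B", -1, pos, logp + lmove)
        elif state == "B":
            for jj in range(L):
                if pos < n:
                    rec("M", jj, pos + 1, logp + lbm + lem[jj, seqi[pos]])
        elif state == "M":
            rec("E", -1, pos, logp + lme[j])
            if j < L - 1:
                if pos < n:
                    rec("M", j + 1, pos + 1, logp + lmm[j] + lem[j + 1, seqi[pos]])
                    rec("I", j, pos + 1, logp + lmi[j] + lei[seqi[pos]])
                rec("D", j + 1, pos, logp + lmd[j])
        elif state == "I":
            if pos < n:
                rec("M", j + 1, pos + 1, logp + lim[j] + lem[j + 1, seqi[pos]])
                rec("I", j, pos + 1, logp + lii[j] + lei[seqi[pos]])
        elif state == "D":
            if j == L - 1:
                rec("E", -1, pos, logp)
            else:
                if pos < n:
                    rec("M", j + 1, pos + 1, logp + ldm[j] + lem[j + 1, seqi[pos]])
                rec("D", j + 1, pos, logp + ldd[j])
        elif state == "E":
            rec("J", -1, pos, logp + lmove)
            rec("C", -1, pos, logp + lmove)
        elif state == "J":
            if pos < n:
                rec("J", -1, pos + 1, logp + lmove + lbg[seqi[pos]])
            rec("B", -1, pos, logp + lmove)
        elif state == "C":
            if pos < n:
                rec("C", -1, pos + 1, logp + lmove + lbg[seqi[pos]])
            else:
                total += math.exp(logp + lmove)

    rec("N", -1, 0, 0.0)
    return math.log(total)


def enumerate_forward_bits(profile, seq: str, epsilon: float = 0.05) -> float:
    tables = profile.score_tables(epsilon)
    lbg = tables[2]
    null = sum(lbg[i] for i in encode(seq))
    return (enumerate_forward_logprob(profile, seq, epsilon) - null) / math.log(2)


def brute_force_similarity(labels1: list[str], labels2: list[str],
                           alpha: float = 0.5) -> float:
    """Literal maximisation over every offset and both orientations."""
    s1, s2 = set(labels1), set(labels2)
    jaccard = len(s1 & s2) / len(s1 | s2)
    best = 0
    for cand in (labels2, labels2[::-1]):
        for off in range(-len(cand), len(labels1) + len(cand)):
            m = sum(1 for i, a in enumerate(labels1)
                    if 0 <= i - off < len(cand) and cand[i - off] == a)
            best = max(best, m)
    order = best / max(len(labels1), len(labels2))
    return alpha * jaccard + (1 - alpha) * order
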