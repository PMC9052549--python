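"""Profile HMMs for BMC component families: building, scoring, searching.

A :class:`ProfileHMM` is a position-specific probabilistic model of one
protein family (e.g. the BMC-H hexamers of one phylogenetic branch), built
from a training alignment with +1/20 emission pseudocounts.  Scoring is
log-odds against a background null model, computed by the forward algorithm
over a multihit local Plan7-style topology (see :mod:`bmctyper._dp`), and is
reported in bits:

    bitscore = log2( P_forward(seq | profile) / P(seq | background) )

A hit is accepted when the bitscore reaches the acceptance threshold
(default 20 bits, configurable per profile or per library).  The scorer is
built in — no external search binary is required — and is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .alphabet import (AA_INDEX, AMINO_ACIDS, GAP_CHARS, N_AA, encode,
                       uniform_background, with_unknown_column)
from .errors import (EmptyResultError, FormatError, InvalidAlignmentError,
                     InvalidSequenceError)
from .roles import Role, classify_role
from . import _dp

#: default per-match-state local exit probability of the search configuration
EXIT_EPSILON = 0.05
#: default acceptance threshold in bits
DEFAULT_BITSCORE_THRESHOLD = 20.0
#: sentinel bmc_type for profiles not trained on a single BMC type
GENERIC = "generic"

LN2 = math.log(2.0)
_LMOVE = math.log(0.5)

# transition column order, fixed across the package
T_MM, T_MI, T_MD, T_IM, T_II, T_DM, T_DD = range(7)


@dataclass
class Hit:
    """A scoring envelope of one profile on one query protein."""

    query_id: str
    profile_name: str
    bitscore: float
    env_start: int  # 1-based inclusive
    env_end: int    # 1-based inclusive
    n_domains: int


@dataclass
class ProfileHMM:
    name: str
    role: Role
    bmc_type: str
    length: int
    match_emissions: np.ndarray   # (L, 20)
    insert_emissions: np.ndarray  # (20,), shared across insert states
    transitions: np.ndarray       # (L, 7): MM MI MD IM II DM DD
    background: np.ndarray        # (20,)
    n_train: int
    bitscore_threshold: float | None = None
    _tables: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.length < 1:
            raise InvalidAlignmentError(f"profile {self.name!r}: length must be >= 1")
        if self.match_emissions.shape != (self.length, N_AA):
            raise InvalidAlignmentError(
                f"profile {self.name!r}: match emission shape "
                f"{self.match_emissions.shape} != ({self.length}, {N_AA})")
        for label, vec in (("match", self.match_emissions),
                           ("insert", self.insert_emissions[None, :]),
                           ("background", self.background[None, :])):
            if np.any(vec <= 0):
                raise InvalidAlignmentError(
                    f"profile {self.name!r}: {label} emissions must be strictly positive")
            if np.any(np.abs(vec.sum(axis=1) - 1.0) > 1e-9):
                raise InvalidAlignmentError(
                    f"profile {self.name!r}: {label} emissions must sum to 1")
        if self.transitions.shape != (self.length, 7):
            raise InvalidAlignmentError(
                f"profile {self.name!r}: transition shape must be ({self.length}, 7)")
        if np.any(self.transitions <= 0):
            raise InvalidAlignmentError(
                f"profile {self.name!r}: transition probabilities must be strictly positive")
        for cols, label in (((T_MM, T_MI, T_MD), "match"), ((T_IM, T_II), "insert"),
                            ((T_DM, T_DD), "delete")):
            sums = self.transitions[:, list(cols)].sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-9):
                raise InvalidAlignmentError(
                    f"profile {self.name!r}: {label}-state transitions must sum to 1")

    # -- scoring ---------------------------------------------------------

    def score_tables(self, epsilon: float = EXIT_EPSILON) -> tuple:
        """Log-space tables of the search-configured model (cached)."""
        if self._tables is not None and self._tables[0] == epsilon:
            return self._tables[1]
        L = self.length
        lem = np.log(np.stack([with_unknown_column(v) for v in self.match_emissions]))
        lei = np.log(with_unknown_column(self.insert_emissions))
        lbg = np.log(with_unknown_column(self.background))
        t = self.transitions
        lmm = np.full(L, _dp.NEG_INF)
        lmi = np.full(L, _dp.NEG_INF)
        lmd = np.full(L, _dp.NEG_INF)
        lme = np.full(L, _dp.NEG_INF)
        lim = np.full(L, _dp.NEG_INF)
        lii = np.full(L, _dp.NEG_INF)
        ldm = np.full(L, _dp.NEG_INF)
        ldd = np.full(L, _dp.NEG_INF)
        if L > 1:
            j = np.arange(L - 1)
            lmm[j] = np.log((1 - epsilon) * t[j, T_MM])
            lmi[j] = np.log((1 - epsilon) * t[j, T_MI])
            lmd[j] = np.log((1 - epsilon) * t[j, T_MD])
            lme[j] = math.log(epsilon)
            lim[j] = np.log(t[j, T_IM])
            lii[j] = np.log(t[j, T_II])
            ldm[j] = np.log(t[j, T_DM])
            ldd[j] = np.log(t[j, T_DD])
        # last match state and D_L exit to E with probability 1
        lme[L - 1] = 0.0
        lbm = -math.log(L)
        tables = (lem, lei, lbg, lmm, lmi, lmd, lme,
                  lim, lii, ldm, ldd, lbm, _LMOVE)
        self._tables = (epsilon, tables)
        return tables

    def consensus(self) -> str:
        """Most probable residue at each match state."""
        return "".join(AMINO_ACIDS[i] for i in self.match_emissions.argmax(axis=1))

    def sample(self, rng: np.random.Generator) -> str:
        """Draw one indel-free sequence from the match-state emissions."""
        return "".join(
            AMINO_ACIDS[rng.choice(N_AA, p=v / v.sum())] for v in self.match_emissions
        )


@dataclass
class ProfileLibrary:
    """A named collection of profiles scored together against queries."""

    profiles: dict[str, ProfileHMM]
    mode: str = GENERIC  # "generic" or "type_specific"
    background: np.ndarray = field(default_factory=uniform_background)
    bitscore_threshold: float = DEFAULT_BITSCORE_THRESHOLD

    def __post_init__(self):
        if self.mode not in (GENERIC, "type_specific"):
            raise ValueError(f"unknown library mode {self.mode!r}")
        if self.mode == "type_specific":
            for p in self.profiles.values():
                if p.bmc_type == GENERIC:
                    raise InvalidAlignmentError(
                        f"type_specific library holds untyped profile {p.name!r}")

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self):
        return iter(self.profiles.values())


# -- construction --------------------------------------------------------

def _normalise_msa(msa) -> list[tuple[str, str]]:
    rows: list[tuple[str, str]] = []
    for i, row in enumerate(msa):
        if isinstance(row, str):
            rows.append((f"row{i}", row.upper()))
        elif isinstance(row, tuple):
            rows.append((str(row[0]), str(row[1]).upper()))
        else:  # SeqRecord-like
            rows.append((str(row.id), str(row.seq).upper()))
    return rows


def build_profile(msa, name: str, role: Role | None = None,
                  bmc_type: str | None = None) -> ProfileHMM:
    """Estimate a ProfileHMM from an aligned protein family.

    Match states are the alignment columns with gap fraction <= 0.5 (a column
    gapped in exactly half the rows is still a match state).  Emissions are
    observed frequencies with a +1/20 pseudocount per residue; transitions are
    counted from the per-row gap structure with +1 smoothing per outcome.
    Deterministic, and invariant to the order of rows.

    ``role``/``bmc_type`` default to what :func:`classify_role` parses from
    ``name``.
    """
    rows = _normalise_msa(msa)
    if not rows:
        raise InvalidAlignmentError("empty alignment: no rows")
    width = len(rows[0][1])
    for rid, rseq in rows:
        if len(rseq) != width:
            raise InvalidAlignmentError(
                f"ragged alignment: row {rid!r} has length {len(rseq)}, expected {width}")
    if width == 0:
        raise InvalidAlignmentError("empty alignment: rows have zero columns")

    n = len(rows)
    is_gap = np.array([[c in GAP_CHARS for c in rseq] for _, rseq in rows])
    gap_frac = is_gap.mean(axis=0)
    match_cols = np.flatnonzero(gap_frac <= 0.5)
    if match_cols.size == 0:
        worst = int(np.argmin(gap_frac))
        raise InvalidAlignmentError(
            f"no match columns: every column has gap fraction > 0.5 "
            f"(least gapped is column {worst + 1} at {gap_frac[worst]:.2f})")
    L = match_cols.size
    col_kind = np.full(width, -1)  # match-state index, or -1 for insert column
    col_kind[match_cols] = np.arange(L)

    m_counts = np.zeros((L, N_AA))
    i_counts = np.zeros(N_AA)
    # transition counts per match position j: MM MI MD IM II DM DD
    t_counts = np.zeros((L, 7))
    for _, rseq in rows:
        # per-row state path through the profile architecture
        path: list[tuple[str, int]] = []
        for c, ch in enumerate(rseq):
            j = col_kind[c]
            if j >= 0:
                if ch in GAP_CHARS:
                    path.append(("D", j))
                else:
                    path.append(("M", j))
                    idx = AA_INDEX.get(ch)
                    if idx is not None:
                        m_counts[j, idx] += 1
            elif ch not in GAP_CHARS:
                # residue in an insert column belongs to the insert state
                # after the previous match position
                prev = path[-1][1] if path else -1
                path.append(("I", prev))
                idx = AA_INDEX.get(ch)
                if idx is not None:
                    i_counts[idx] += 1
        for (s1, j1), (s2, _) in zip(path, path[1:]):
            if j1 < 0:
                continue  # insert before the first match state
            if s1 == "M":
                if s2 == "M":
                    t_counts[j1, T_MM] += 1
                elif s2 == "I":
                    t_counts[j1, T_MI] += 1
                else:
                    t_counts[j1, T_MD] += 1
            elif s1 == "I":
                if s2 == "M":
                    t_counts[j1, T_IM] += 1
                elif s2 == "I":
                    t_counts[j1, T_II] += 1
                # I->D is outside the topology: not counted
            else:  # D
                if s2 == "M":
                    t_counts[j1, T_DM] += 1
                elif s2 == "D":
                    t_counts[j1, T_DD] += 1
                # D->I is outside the topology: not counted

    m_em = (m_counts + 1.0 / N_AA)
    m_em /= m_em.sum(axis=1, keepdims=True)
    i_em = i_counts + 1.0 / N_AA
    i_em /= i_em.sum()

    trans = t_counts + 1.0
    for cols in ((T_MM, T_MI, T_MD), (T_IM, T_II), (T_DM, T_DD)):
        cols = list(cols)
        trans[:, cols] /= trans[:, cols].sum(axis=1, keepdims=True)

    if role is None or bmc_type is None:
        parsed_role, parsed_type = classify_role(name)
        role = role if role is not None else parsed_role
        bmc_type = bmc_type if bmc_type is not None else (parsed_type or GENERIC)

    return ProfileHMM(name=name, role=role, bmc_type=bmc_type, length=L,
                      match_emissions=m_em, insert_emissions=i_em,
                      transitions=trans, background=uniform_background(),
                      n_train=n)


# -- scoring -------------------------------------------------------------

def forward_bitscore(profile: ProfileHMM, seq: str,
                     epsilon: float = EXIT_EPSILON) -> float:
    """Forward log-odds score in bits (no thresholding)."""
    if not seq:
        raise InvalidSequenceError("cannot score an empty sequence")
    seqi = encode(seq)
    tables = profile.score_tables(epsilon)
    logp = _dp.forward_logprob(seqi, *tables)
    lbg = tables[2]
    null = float(lbg[seqi].sum())
    return (logp - null) / LN2


def viterbi_bitscore(profile: ProfileHMM, seq: str,
                     epsilon: float = EXIT_EPSILON) -> float:
    """Single-best-path log-odds score in bits."""
    if not seq:
        raise InvalidSequenceError("cannot score an empty sequence")
    seqi = encode(seq)
    tables = profile.score_tables(epsilon)
    *_, score = _dp.viterbi_matrices(seqi, *tables)
    lbg = tables[2]
    null = float(lbg[seqi].sum())
    return (score - null) / LN2


def _viterbi_envelope(profile: ProfileHMM, seqi: np.ndarray,
                      epsilon: float) -> tuple[int, int, int]:
    """(env_start, env_end, n_domains) from the Viterbi traceback."""
    tables = profile.score_tables(epsilon)
    (lem, lei, lbg, lmm, lmi, lmd, lme, lim, lii, ldm, ldd, lbm, lmove) = tables
    VM, VI, VD, VN, VB, VJ, VC, VE, _ = _dp.viterbi_matrices(seqi, *tables)
    n = len(seqi)
    L = profile.length

    emitted: list[int] = []
    n_domains = 0
    state, j, i = "C", -1, n
    while True:
        if state == "C":
            from_e = VE[i] + lmove
            from_loop = VC[i - 1] + lmove + lbg[seqi[i - 1]] if i >= 1 else _dp.NEG_INF
            if from_e >= from_loop:
                state = "E"
            else:
                i -= 1
        elif state == "E":
            cands = [VM[i, jj] + lme[jj] for jj in range(L)]
            if L > 1:
                cands.append(VD[i, L - 1])
            k = int(np.argmax(cands))
            if k < L:
                state, j = "M", k
            else:
                state, j = "D", L - 1
        elif state == "M":
            emitted.append(i)
            cands = [VB[i - 1] + lbm]
            if j > 0:
                cands += [VM[i - 1, j - 1] + lmm[j - 1],
                          VI[i - 1, j - 1] + lim[j - 1],
                          VD[i - 1, j - 1] + ldm[j - 1]]
            k = int(np.argmax(cands))
            i -= 1
            if k == 0:
                n_domains += 1
                state = "B"
            elif k == 1:
                state, j = "M", j - 1
            elif k == 2:
                state, j = "I", j - 1
            else:
                state, j = "D", j - 1
        elif state == "I":
            emitted.append(i)
            a = VM[i - 1, j] + lmi[j]
            b = VI[i - 1, j] + lii[j]
            i -= 1
            state = "M" if a >= b else "I"
        elif state == "D":
            a = VM[i, j - 1] + lmd[j - 1]
            b = VD[i, j - 1] + ldd[j - 1]
            state, j = ("M", j - 1) if a >= b else ("D", j - 1)
        elif state == "B":
            if VN[i] + lmove >= VJ[i] + lmove:
                break  # reached the N flank: no earlier domain
            state = "J"
        elif state == "J":
            from_e = VE[i] + lmove
            from_loop = VJ[i - 1] + lmove + lbg[seqi[i - 1]] if i >= 1 else _dp.NEG_INF
            if from_e >= from_loop:
                state = "E"
            else:
                i -= 1
    if not emitted:  # pragma: no cover - an accepted hit always emits
        return 1, n, max(n_domains, 1)
    return min(emitted), max(emitted), max(n_domains, 1)


def score_sequence(profile: ProfileHMM, seq: str, query_id: str = "query",
                   threshold: float | None = None,
                   epsilon: float = EXIT_EPSILON) -> Hit | None:
    """Score one protein against one profile; None below the threshold."""
    if not seq:
        raise InvalidSequenceError(
            f"cannot score empty sequence for query {query_id!r}")
    if threshold is None:
        threshold = (profile.bitscore_threshold
                     if profile.bitscore_threshold is not None
                     else DEFAULT_BITSCORE_THRESHOLD)
    bits = forward_bitscore(profile, seq, epsilon)
    if bits < threshold:
        return None
    env_start, env_end, n_domains = _viterbi_envelope(profile, encode(seq), epsilon)
    return Hit(query_id=query_id, profile_name=profile.name, bitscore=bits,
               env_start=env_start, env_end=env_end, n_domains=n_domains)


def search(library: ProfileLibrary, records: Sequence,
           threshold: float | None = None) -> list[list[Hit]]:
    """Score every record against every profile in the library.

    ``records`` is an ordered sequence of objects with ``id`` and ``seq``
    attributes (see :class:`bmctyper.locus.ProteinRecord`).  Returns one list
    of accepted hits per record, in input order; records with no accepted
    hit contribute an empty list.
    """
    if len(records) == 0:
        raise EmptyResultError("search requires at least one protein record")
    if len(library) == 0:
        raise EmptyResultError("search requires a non-empty profile library")
    out: list[list[Hit]] = []
    profs = sorted(library.profiles.values(), key=lambda p: p.name)
    for rec in records:
        if not rec.seq:
            raise InvalidSequenceError(f"record {rec.id!r} has an empty sequence")
        seqi = encode(rec.seq)
        null_cache: dict[int, float] = {}
        hits: list[Hit] = []
        for prof in profs:
            thr = threshold
            if thr is None:
                thr = (prof.bitscore_threshold
                       if prof.bitscore_threshold is not None
                       else library.bitscore_threshold)
            tables = prof.score_tables()
            logp = _dp.forward_logprob(seqi, *tables)
            null = float(tables[2][seqi].sum())
            bits = (logp - null) / LN2
            if bits >= thr:
                es, ee, nd = _viterbi_envelope(prof, seqi, EXIT_EPSILON)
                hits.append(Hit(rec.id, prof.name, bits, es, ee, nd))
        out.append(hits)
    return out


# -- native serialization ------------------------------------------------

_LIB_MAGIC = "# bmctyper profile library v1"


def _fmt_vec(v: np.ndarray) -> str:
    return ",".join(repr(float(x)) for x in v)


def save_library(library: ProfileLibrary, stream) -> None:
    """Write a library as the documented plain-text format (exact round-trip)."""
    close = False
    if isinstance(stream, str):
        stream, close = open(stream, "w"), True
    try:
        w = stream.write
        w(_LIB_MAGIC + "\n")
        w(f"mode\t{library.mode}\n")
        w(f"threshold\t{library.bitscore_threshold!r}\n")
        w(f"background\t{_fmt_vec(library.background)}\n")
        for name in sorted(library.profiles):
            p = library.profiles[name]
            thr = "" if p.bitscore_threshold is None else repr(p.bitscore_threshold)
            w(f"profile\t{p.name}\t{p.role.name}\t{p.bmc_type}\t{p.length}"
              f"\t{p.n_train}\t{thr}\n")
            for j in range(p.length):
                w(f"match\t{_fmt_vec(p.match_emissions[j])}\n")
            w(f"insert\t{_fmt_vec(p.insert_emissions)}\n")
            for j in range(p.length):
                w(f"trans\t{_fmt_vec(p.transitions[j])}\n")
            w("endprofile\n")
    finally:
        if close:
            stream.close()


def load_library(stream) -> ProfileLibrary:
    """Read a library written by :func:`save_library`."""
    close = False
    if isinstance(stream, str):
        stream, close = open(stream), True
    try:
        lines = stream.read().splitlines()
    finally:
        if close:
            stream.close()
    if not lines or lines[0].strip() != _LIB_MAGIC:
        raise FormatError("not a bmctyper profile library (bad magic line)", line=1)
    mode, threshold, background = GENERIC, DEFAULT_BITSCORE_THRESHOLD, uniform_background()
    profiles: dict[str, ProfileHMM] = {}
    i = 1
    n_lines = len(lines)

    def parse_vec(text: str, lineno: int) -> np.ndarray:
        try:
            return np.array([float(x) for x in text.split(",")])
        except ValueError as exc:
            raise FormatError(f"bad float vector: {exc}", line=lineno) from None

    while i < n_lines:
        line = lines[i]
        if not line.strip() or line.startswith("#"):
            i += 1
            continue
        fields = line.split("\t")
        tag = fields[0]
        if tag == "mode":
            mode = fields[1]
        elif tag == "threshold":
            threshold = float(fields[1])
        elif tag == "background":
            background = parse_vec(fields[1], i + 1)
        elif tag == "profile":
            if len(fields) < 7:
                raise FormatError("truncated profile header", line=i + 1)
            name, role_name, bmc_type = fields[1], fields[2], fields[3]
            length, n_train = int(fields[4]), int(fields[5])
            thr = float(fields[6]) if fields[6] else None
            m_rows, t_rows, ins = [], [], None
            i += 1
            while i < n_lines and lines[i] != "endprofile":
                f2 = lines[i].split("\t")
                if f2[0] == "match":
                    m_rows.append(parse_vec(f2[1], i + 1))
                elif f2[0] == "insert":
                    ins = parse_vec(f2[1], i + 1)
                elif f2[0] == "trans":
                    t_rows.append(parse_vec(f2[1], i + 1))
                else:
                    raise FormatError(f"unexpected record {f2[0]!r} inside profile",
                                      line=i + 1)
                i += 1
            if i >= n_lines:
                raise FormatError(f"profile {name!r} missing endprofile", line=n_lines)
            if len(m_rows) != length or len(t_rows) != length or ins is None:
                raise FormatError(f"profile {name!r} body does not match length "
                                  f"{length}", line=i + 1)
            if name in profiles:
                raise FormatError(f"duplicate profile name {name!r}", line=i + 1)
            profiles[name] = ProfileHMM(
                name=name, role=Role[role_name], bmc_type=bmc_type, length=length,
                match_emissions=np.array(m_rows), insert_emissions=ins,
                transitions=np.array(t_rows), background=background.copy(),
                n_train=n_train, bitscore_threshold=thr)
        else:
            raise FormatError(f"unexpected record {tag!r}", line=i + 1)
        i += 1
    return ProfileLibrary(profiles=profiles, mode=mode, background=background,
                          bitscore_threshold=threshold)
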