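"""HMMER3/f ASCII profile interchange.

Import goes through pyhmmer's parser (the reference implementation of the
format); a light pre-scan first checks the header magic and the ``//``
record terminators so malformed files are rejected with a line number.
Export writes the subset of the format this package uses (amino alphabet,
probabilities as negative natural logs) and is validated by re-parsing.
"""

from __future__ import annotations

import io
import math

import numpy as np
import pyhmmer

from .alphabet import AMINO_ACIDS, N_AA, uniform_background
from .errors import FormatError
from .profiles import GENERIC, ProfileHMM, ProfileLibrary
from .roles import classify_role

_STAR = "*"
_MIN_P = 1e-9


def _score(p: float) -> str:
    if p <= 0:
        return f"{_STAR:>8s}"
    return f"{-math.log(p):8.5f}"


def export_hmmer3(library: ProfileLibrary) -> str:
    """Render every profile as a HMMER3/f ASCII record."""
    out = io.StringIO()
    for name in sorted(library.profiles):
        p = library.profiles[name]
        w = out.write
        w("HMMER3/f [bmctyper | profile export]\n")
        w(f"NAME  {p.name}\n")
        w(f"LENG  {p.length}\n")
        w("ALPH  amino\n")
        w("RF    no\nMM    no\nCONS  yes\nCS    no\nMAP   yes\n")
        w("HMM     ")
        w("".join(f"{aa:>9s}" for aa in AMINO_ACIDS))
        w("\n")
        w("        " + "".join(f"{t:>9s}" for t in
                               ("m->m", "m->i", "m->d", "i->m", "i->i",
                                "d->m", "d->d")) + "\n")
        w("  COMPO " + " ".join(_score(x) for x in p.background) + "\n")
        # node 0: insert-state emissions, then B-state transitions
        w("        " + " ".join(_score(x) for x in p.insert_emissions) + "\n")
        t0 = (0.99, 0.005, 0.005, 0.5, 0.5, 1.0, 0.0)
        w("        " + " ".join(_score(x) for x in t0) + "\n")
        cons = p.consensus()
        for k in range(1, p.length + 1):
            em = p.match_emissions[k - 1]
            w(f"{k:7d} " + " ".join(_score(x) for x in em))
            w(f" {k:6d} {cons[k - 1].lower()} - - -\n")
            w("        " + " ".join(_score(x) for x in p.insert_emissions) + "\n")
            if k < p.length:
                tr = p.transitions[k - 1]
                w("        " + " ".join(_score(x) for x in tr) + "\n")
            else:
                w("        " + " ".join(
                    _score(x) for x in (1.0, 0.0, 0.0, 1.0, 0.0, 1.0, 0.0)) + "\n")
        w("//\n")
    return out.getvalue()


def _prescan(text: str) -> None:
    lines = text.splitlines()
    first = None
    for i, line in enumerate(lines):
        if line.strip():
            first = i
            break
    if first is None:
        raise FormatError("empty HMMER3 input", line=1)
    if not lines[first].startswith("HMMER3"):
        raise FormatError(
            f"not a HMMER3 ASCII profile (got {lines[first][:20]!r})", line=first + 1)
    open_at = None
    for i, line in enumerate(lines):
        s = line.strip()
        if s.startswith("HMMER3"):
            if open_at is not None:
                raise FormatError(
                    f"record starting at line {open_at + 1} not terminated by '//'",
                    line=i + 1)
            open_at = i
        elif s == "//":
            open_at = None
    if open_at is not None:
        raise FormatError(
            f"record starting at line {open_at + 1} not terminated by '//'",
            line=len(lines))


def _renorm(rows: np.ndarray, groups) -> np.ndarray:
    rows = np.clip(rows, _MIN_P, None)
    for cols in groups:
        cols = list(cols)
        rows[:, cols] /= rows[:, cols].sum(axis=1, keepdims=True)
    return rows


def import_hmmer3(source) -> ProfileLibrary:
    """Parse a HMMER3/f ASCII stream into a ProfileLibrary.

    ``source`` may be text, a text stream, or a path.  Profile names are
    preserved; role and BMC type are parsed from the name when it follows
    the ``<TYPE>__<ROLE>_<color>`` convention.  Stored zero probabilities
    (``*`` scores) are clipped to a tiny floor and renormalised so the
    resulting profiles satisfy the strict-positivity invariant.
    """
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str) and "\n" not in source and not source.startswith("HMMER3"):
        with open(source) as fh:
            text = fh.read()
    else:
        text = source
    _prescan(text)
    profiles: dict[str, ProfileHMM] = {}
    try:
        with pyhmmer.plan7.HMMFile(io.BytesIO(text.encode())) as hmm_file:
            hmms = list(hmm_file)
    except ValueError as exc:
        raise FormatError(f"pyhmmer rejected the profile stream: {exc}") from exc
    for hmm in hmms:
        name = hmm.name.decode() if isinstance(hmm.name, bytes) else str(hmm.name)
        M = hmm.M
        me = np.asarray(hmm.match_emissions, dtype=float)[1:, :N_AA]
        me = np.clip(me, _MIN_P, None)
        me /= me.sum(axis=1, keepdims=True)
        ie = np.asarray(hmm.insert_emissions, dtype=float)[1:, :N_AA].mean(axis=0)
        ie = np.clip(ie, _MIN_P, None)
        ie /= ie.sum()
        tr = np.asarray(hmm.transition_probabilities, dtype=float)[1:, :]
        tr = _renorm(tr, ((0, 1, 2), (3, 4), (5, 6)))
        role, bmc_type = classify_role(name)
        if name in profiles:
            raise FormatError(f"duplicate profile name {name!r} in HMMER3 input")
        profiles[name] = ProfileHMM(
            name=name, role=role, bmc_type=bmc_type or GENERIC, length=M,
            match_emissions=me, insert_emissions=ie, transitions=tr,
            background=uniform_background(), n_train=max(int(hmm.nseq or 0), 0) or 1)
    return ProfileLibrary(profiles=profiles, mode=GENERIC)
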