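"""Ordered protein input and candidate-locus delimitation.

The input contract mirrors how BMC loci are analysed in practice: a
multi-FASTA whose records appear in the same order as the genes on the
genome.  For whole proteomes, candidate loci are the windows of +/- 12 genes
(by default) around each detected shell protein, merged when they overlap or
touch.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import EmptyResultError, FastaError


@dataclass
class ProteinRecord:
    """One protein in genome order (index is the 0-based gene position)."""

    id: str
    description: str
    index: int
    seq: str


@dataclass
class CandidateLocus:
    """A merged window of genes around one or more shell-protein hits."""

    records: list[ProteinRecord]
    anchor_indices: list[int]  # proteome indices of the seeding shell hits
    window: int
    start: int  # proteome index of the first gene (0-based, inclusive)
    end: int    # proteome index of the last gene (0-based, inclusive)

    def __post_init__(self):
        if not self.anchor_indices:
            raise ValueError("a CandidateLocus needs at least one anchor")
        for a in self.anchor_indices:
            if not self.start <= a <= self.end:
                raise ValueError(f"anchor {a} outside locus [{self.start}, {self.end}]")


def read_multifasta(source) -> list[ProteinRecord]:
    """Parse ordered protein records from a multi-FASTA path, text or stream.

    Sequences are upper-cased; a single trailing ``*`` stop symbol is
    stripped; CRLF line endings are tolerated.  Duplicate ids, empty
    sequences, or an input without any record are rejected.
    """
    if hasattr(source, "read"):
        handle = source
    elif isinstance(source, str) and (
            source.lstrip().startswith(">") or "\n" in source):
        handle = io.StringIO(source)
    elif isinstance(source, str) and not os.path.exists(source):
        # neither FASTA text nor an existing file: let the parser report it
        # unless it clearly looks like a path
        if os.sep in source or source.endswith((".fa", ".faa", ".fasta")):
            raise FileNotFoundError(source)
        handle = io.StringIO(source)
    else:
        handle = open(source)
    try:
        records: list[ProteinRecord] = []
        seen: set[str] = set()
        try:
            parsed = list(SeqIO.parse(handle, "fasta"))
        except ValueError as exc:
            raise FastaError(f"no FASTA records found in input ({exc})") from None
        for rec in parsed:
            if rec.id in seen:
                raise FastaError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)
            seq = str(rec.seq).upper()
            if seq.endswith("*"):
                seq = seq[:-1]
            if not seq:
                raise FastaError(f"record {rec.id!r} has an empty sequence")
            desc = rec.description[len(rec.id):].strip()
            records.append(ProteinRecord(id=rec.id, description=desc,
                                         index=len(records), seq=seq))
    finally:
        if handle is not source:
            handle.close()
    if not records:
        raise FastaError("no FASTA records found in input")
    return records


def write_multifasta(records: Iterable[ProteinRecord], stream) -> None:
    """Write records back out as multi-FASTA (id + description headers)."""
    close = False
    if isinstance(stream, str):
        stream, close = open(stream, "w"), True
    try:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            stream.write(f">{header}\n")
            for i in range(0, len(rec.seq), 60):
                stream.write(rec.seq[i:i + 60] + "\n")
    finally:
        if close:
            stream.close()


def extract_neighborhoods(records: Sequence[ProteinRecord],
                          shell_hit_indices: Iterable[int],
                          window: int = 12) -> list[CandidateLocus]:
    """Expand each shell hit to [i-window, i+window] and merge the intervals.

    Intervals that overlap or touch (gap of zero genes) merge into a single
    candidate locus; the result is sorted by start position.  An empty hit
    set yields an empty list.
    """
    if window < 0:
        raise ValueError(f"window must be >= 0, got {window}")
    n = len(records)
    hits = sorted(set(int(i) for i in shell_hit_indices))
    for i in hits:
        if not 0 <= i < n:
            raise ValueError(f"shell hit index {i} outside proteome of {n}")
    loci: list[CandidateLocus] = []
    cur: tuple[int, int, list[int]] | None = None
    for i in hits:
        lo, hi = max(0, i - window), min(n - 1, i + window)
        if cur is not None and lo <= cur[1] + 1:
            cur = (cur[0], max(cur[1], hi), cur[2] + [i])
        else:
            if cur is not None:
                loci.append(_make_locus(records, cur, window))
            cur = (lo, hi, [i])
    if cur is not None:
        loci.append(_make_locus(records, cur, window))
    return loci


def _make_locus(records, interval, window) -> CandidateLocus:
    lo, hi, anchors = interval
    return CandidateLocus(records=list(records[lo:hi + 1]),
                          anchor_indices=anchors, window=window,
                          start=lo, end=hi)
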