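"""Reference registry of BMC types/subtypes with example-locus fingerprints.

The shipped default registry enumerates the 68 functional types and subtypes
of the published BMC classification scheme (carboxysomes plus the EUT, PDU,
GRM, SPU, CUT, PVM, RMM, ACI, ETU, MUF, MIC and BUF metabolosome series).
Its example fingerprints are synthetic placeholders — deterministic
role-label sequences, one color per type — that stand in until real locus
fingerprints are loaded; the data file says so in its header.

The registry format is a single structured text file (TSV):

    type_id <TAB> description <TAB> components <TAB> fingerprints <TAB> sequences

* components: comma-separated profile names commonly present;
* fingerprints: one or more example fingerprints, labels comma-separated,
  examples separated by ``|`` (at least one required);
* sequences: optional ``id:SEQ`` pairs separated by ``;`` for FASTA export.
"""

from __future__ import annotations

import io
import statistics
from dataclasses import dataclass, field
from importlib import resources

from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint

from .errors import FormatError, RegistryError
from .fingerprint import Fingerprint
from .locus import ProteinRecord, write_multifasta

_MAGIC = "# bmctyper type registry v1"


@dataclass
class TypeRegistryEntry:
    type_id: str
    description: str
    example_fingerprints: list[Fingerprint]
    component_inventory: list[str]
    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.example_fingerprints:
            raise RegistryError(
                f"type {self.type_id!r} has no example fingerprint")


@dataclass
class TypeRegistry:
    entries: dict[str, TypeRegistryEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, type_id: str) -> bool:
        return type_id in self.entries

    def example_fingerprint_map(self) -> dict[str, list[Fingerprint]]:
        return {tid: e.example_fingerprints for tid, e in self.entries.items()}


def load_registry(source) -> TypeRegistry:
    """Load a registry from a path, text, or stream in the documented format."""
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str) and "\n" in source:
        text = source
    else:
        with open(source) as fh:
            text = fh.read()
    lines = text.splitlines()
    if not lines or lines[0].strip() != _MAGIC:
        raise FormatError("not a bmctyper type registry (bad magic line)", line=1)
    entries: dict[str, TypeRegistryEntry] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise FormatError(f"registry row needs >= 4 columns, got {len(fields)}",
                              line=lineno)
        type_id, description, components, fps = fields[:4]
        seqs = fields[4] if len(fields) > 4 else ""
        if type_id in entries:
            raise RegistryError(f"duplicate type_id {type_id!r} (line {lineno})")
        fingerprints = []
        for i, fp in enumerate(x for x in fps.split("|") if x):
            labels = [l for l in fp.split(",") if l]
            if labels:
                fingerprints.append(Fingerprint(labels=labels,
                                                locus_id=f"{type_id}_example{i + 1}"))
        if not fingerprints:
            raise RegistryError(
                f"type {type_id!r} has no example fingerprint (line {lineno})")
        sequences: dict[str, str] = {}
        for pair in (p for p in seqs.split(";") if p):
            if ":" not in pair:
                raise FormatError(f"bad sequence entry {pair!r}", line=lineno)
            sid, sseq = pair.split(":", 1)
            sequences[sid] = sseq
        entries[type_id] = TypeRegistryEntry(
            type_id=type_id, description=description,
            example_fingerprints=fingerprints,
            component_inventory=[c for c in components.split(",") if c],
            sequences=sequences)
    return TypeRegistry(entries=entries)


def save_registry(registry: TypeRegistry, stream) -> None:
    close = False
    if isinstance(stream, str):
        stream, close = open(stream, "w"), True
    try:
        stream.write(_MAGIC + "\n")
        for tid in sorted(registry.entries):
            e = registry.entries[tid]
            fps = "|".join(",".join(fp.labels) for fp in e.example_fingerprints)
            seqs = ";".join(f"{sid}:{seq}" for sid, seq in sorted(e.sequences.items()))
            stream.write("\t".join([e.type_id, e.description,
                                    ",".join(e.component_inventory), fps, seqs]) + "\n")
    finally:
        if close:
            stream.close()


def default_registry() -> TypeRegistry:
    """The shipped 68-type registry."""
    data = resources.files("bmctyper").joinpath("data/bmc_types.tsv").read_text()
    return load_registry(data)


def list_types(registry: TypeRegistry, filter: str | None = None,
               ) -> list[TypeRegistryEntry]:
    """Entries in lexicographic order, optionally filtered by case-insensitive
    substring match on the type id."""
    entries = [registry.entries[tid] for tid in sorted(registry.entries)]
    if filter:
        needle = filter.lower()
        entries = [e for e in entries if needle in e.type_id.lower()]
    return entries


def export_type(registry: TypeRegistry, type_id: str) -> tuple[str, str]:
    """(multi-FASTA text, fingerprint text) for one type's attached sequences."""
    if type_id not in registry.entries:
        raise RegistryError(f"unknown type_id {type_id!r}")
    entry = registry.entries[type_id]
    if not entry.sequences:
        raise RegistryError(f"type {type_id!r} has no sequences attached")
    records = [ProteinRecord(id=sid, description="", index=i, seq=seq)
               for i, (sid, seq) in enumerate(sorted(entry.sequences.items()))]
    buf = io.StringIO()
    write_multifasta(records, buf)
    fp_text = "\n".join(",".join(fp.labels) for fp in entry.example_fingerprints) + "\n"
    return buf.getvalue(), fp_text


def profile_stats(sequences: dict[str, str]) -> dict[str, float | int]:
    """Count, length and isoelectric-point summary for a sequence set.

    pI is computed by the standard Henderson-Hasselbalch bisection
    (Biopython's IsoelectricPoint, Bjellqvist pKa set).
    """
    if not sequences:
        raise RegistryError("no sequences to summarise")
    lengths = [len(s) for s in sequences.values()]
    pis = [IsoelectricPoint(s).pi() for s in sequences.values()]
    return {
        "count": len(sequences),
        "length_min": min(lengths),
        "length_mean": statistics.fmean(lengths),
        "length_max": max(lengths),
        "pi_min": min(pis),
        "pi_mean": statistics.fmean(pis),
        "pi_max": max(pis),
    }
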