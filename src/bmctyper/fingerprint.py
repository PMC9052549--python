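"""Locus fingerprints, inventory+order similarity, ranking, clustering, and
majority-vote BMC type calling.

A fingerprint is the ordered list of best-hit profile names along a locus.
Two fingerprints are compared by blending their component *inventory*
(Jaccard index of the label sets) with their component *order* (the best
label-match fraction over all alignment offsets, searching both the forward
and the reversed orientation of the second locus, since operons sit on
either strand):

    S = alpha * Jaccard + (1 - alpha) * max_offset,orient matches / max(|f1|, |f2|)

with alpha = 0.5 by default.  The BMC type of a locus is called by majority
vote over the BMC types of its typed assignments; a locus whose votes have
no unique majority is reported ambiguous, and a locus without any shell
assignment is reported no_shell.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx

from .errors import EmptyResultError
from .roles import Role, SHELL_ROLES

DEFAULT_ALPHA = 0.5
DEFAULT_MAJORITY = 0.5
DEFAULT_CLUSTER_THRESHOLD = 0.6
DEFAULT_K = 5


@dataclass
class Fingerprint:
    labels: list[str]
    locus_id: str

    def __post_init__(self):
        if not self.labels:
            raise EmptyResultError(
                f"locus {self.locus_id!r}: nothing to fingerprint (no labels)")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class SimilarityScore:
    value: float
    inventory_component: float
    order_component: float
    best_offset: int
    orientation: str  # "forward" or "reversed"


@dataclass
class TypeAssignment:
    bmc_type: str | None
    confidence: float
    status: str  # "assigned" | "ambiguous" | "no_shell"
    vote_table: dict[str, int]
    signature_types: list[str] = field(default_factory=list)


def make_fingerprint(assignments: Sequence, locus_id: str) -> Fingerprint:
    """Profile names of assigned proteins, in locus order; NONE excluded."""
    labels = [a.profile_name for a in assignments if a.role is not Role.NONE]
    if not labels:
        raise EmptyResultError(
            f"locus {locus_id!r}: nothing to fingerprint (no assigned proteins)")
    return Fingerprint(labels=labels, locus_id=locus_id)


def _best_order(f1: list[str], f2: list[str]) -> tuple[int, int]:
    """(max matches, best offset): f1[i] is compared with f2[i - offset]."""
    n1, n2 = len(f1), len(f2)
    best, best_off = -1, 0
    for off in range(-(n2 - 1), n1):
        m = 0
        for i in range(max(0, off), min(n1, n2 + off)):
            if f1[i] == f2[i - off]:
                m += 1
        if m > best:
            best, best_off = m, off
    return best, best_off


def similarity(f1: Fingerprint, f2: Fingerprint, alpha: float = DEFAULT_ALPHA,
               search_reverse: bool = True) -> SimilarityScore:
    """Inventory+order correlation score between two loci, in [0, 1]."""
    if not f1.labels or not f2.labels:
        raise EmptyResultError("cannot compare an empty fingerprint")
    s1, s2 = set(f1.labels), set(f2.labels)
    inventory = len(s1 & s2) / len(s1 | s2)
    denom = max(len(f1), len(f2))
    fwd_m, fwd_off = _best_order(f1.labels, f2.labels)
    orient, matches, offset = "forward", fwd_m, fwd_off
    if search_reverse:
        rev_m, rev_off = _best_order(f1.labels, f2.labels[::-1])
        if rev_m > fwd_m:
            orient, matches, offset = "reversed", rev_m, rev_off
    order = matches / denom
    return SimilarityScore(value=alpha * inventory + (1 - alpha) * order,
                           inventory_component=inventory, order_component=order,
                           best_offset=offset, orientation=orient)


def rank_closest(f: Fingerprint, registry, k: int = DEFAULT_K,
                 alpha: float = DEFAULT_ALPHA) -> list[tuple[str, SimilarityScore]]:
    """Top-k reference types by the best-matching example fingerprint.

    ``registry`` maps type id -> iterable of example fingerprints (a
    :class:`bmctyper.registry.TypeRegistry` works directly).  Sorted by
    value descending; ties break lexicographically on the type id.
    """
    items = _registry_items(registry)
    if not items:
        raise EmptyResultError("reference registry is empty")
    scored: list[tuple[str, SimilarityScore]] = []
    for type_id, examples in items:
        best: SimilarityScore | None = None
        for ex in examples:
            s = similarity(f, ex, alpha=alpha)
            if best is None or s.value > best.value:
                best = s
        if best is not None:
            scored.append((type_id, best))
    scored.sort(key=lambda ts: (-ts[1].value, ts[0]))
    return scored[:k]


def _registry_items(registry):
    if hasattr(registry, "example_fingerprint_map"):
        return sorted(registry.example_fingerprint_map().items())
    if isinstance(registry, Mapping):
        return sorted(registry.items())
    return sorted(registry)


def cluster_loci(fingerprints: Sequence[Fingerprint],
                 threshold: float = DEFAULT_CLUSTER_THRESHOLD,
                 alpha: float = DEFAULT_ALPHA) -> list[list[str]]:
    """Single-linkage clusters: connected components of the similarity graph.

    An edge joins two loci when their similarity reaches ``threshold``.
    Clusters are returned as sorted lists of locus ids, ordered by their
    smallest member.
    """
    if not fingerprints:
        raise EmptyResultError("no fingerprints to cluster")
    g = nx.Graph()
    g.add_nodes_from(f.locus_id for f in fingerprints)
    for i, fa in enumerate(fingerprints):
        for fb in fingerprints[i + 1:]:
            if similarity(fa, fb, alpha=alpha).value >= threshold:
                g.add_edge(fa.locus_id, fb.locus_id)
    clusters = [sorted(c) for c in nx.connected_components(g)]
    clusters.sort(key=lambda c: c[0])
    return clusters


def call_type(assignments: Sequence, majority: float = DEFAULT_MAJORITY,
              shell_only: bool = False) -> TypeAssignment:
    """Majority-vote BMC type over the typed assignments of a locus.

    Every assignment carrying a BMC type votes (optionally shell roles
    only).  A unique modal type reaching the majority fraction is assigned
    with confidence modal/total; otherwise the call is ambiguous.  A locus
    with no shell-role assignment at all is no_shell.  When the call is
    ambiguous, the types of any signature-enzyme assignments are listed as a
    functional hint.
    """
    has_shell = any(a.role in SHELL_ROLES for a in assignments)
    voters = [a for a in assignments
              if a.bmc_type and (not shell_only or a.role in SHELL_ROLES)]
    votes = Counter(a.bmc_type for a in voters)
    table = dict(sorted(votes.items()))
    if not has_shell:
        return TypeAssignment(bmc_type=None, confidence=0.0, status="no_shell",
                              vote_table=table)
    sig_types = sorted({a.bmc_type for a in assignments
                        if a.role is Role.SIGNATURE_ENZYME and a.bmc_type})
    if not votes:
        return TypeAssignment(bmc_type=None, confidence=0.0, status="ambiguous",
                              vote_table=table, signature_types=sig_types)
    total = sum(votes.values())
    (top_type, top_n), = votes.most_common(1)
    modal = [t for t, n in votes.items() if n == top_n]
    confidence = top_n / total
    if len(modal) == 1 and confidence >= majority:
        return TypeAssignment(bmc_type=top_type, confidence=confidence,
                              status="assigned", vote_table=table)
    return TypeAssignment(bmc_type=None, confidence=confidence,
                          status="ambiguous", vote_table=table,
                          signature_types=sig_types)


def closest_table(ranking: Sequence[tuple[str, SimilarityScore]]) -> str:
    """Render a rank_closest result as the TSV closest-types report."""
    lines = ["rank\tbmc_type\tvalue\tinventory\torder\toffset\torientation"]
    for rank, (type_id, s) in enumerate(ranking, start=1):
        lines.append(f"{rank}\t{type_id}\t{s.value:.4f}\t{s.inventory_component:.4f}"
                     f"\t{s.order_component:.4f}\t{s.best_offset}\t{s.orientation}")
    return "\n".join(lines) + "\n"


def type_call_table(call: TypeAssignment) -> str:
    """Render a TypeAssignment as the type-call report."""
    lines = [f"status\t{call.status}",
             f"bmc_type\t{call.bmc_type or ''}",
             f"confidence\t{call.confidence:.4f}",
             "vote_table\t" + ",".join(f"{t}:{n}" for t, n in call.vote_table.items())]
    if call.signature_types:
        lines.append("signature_enzyme_types\t" + ",".join(call.signature_types))
    return "\n".join(lines) + "\n"
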