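"""End-to-end locus analysis and fixture-world evaluation helpers."""

from __future__ import annotations

from dataclasses import dataclass

from .annotate import BestAssignment, assign_best
from .errors import EmptyResultError
from .fingerprint import (DEFAULT_ALPHA, DEFAULT_K, DEFAULT_MAJORITY,
                          Fingerprint, SimilarityScore, TypeAssignment,
                          call_type, make_fingerprint, rank_closest)
from .profiles import ProfileLibrary, search
from .registry import TypeRegistry
from .roles import Role
from .simulate import FixtureWorld, build_library, make_registry


@dataclass
class LocusResult:
    assignments: list[BestAssignment]
    type_call: TypeAssignment
    fingerprint: Fingerprint | None
    closest: list[tuple[str, SimilarityScore]] | None


def analyse_locus(records, library: ProfileLibrary,
                  registry: TypeRegistry | None = None,
                  threshold: float | None = None,
                  alpha: float = DEFAULT_ALPHA,
                  majority: float = DEFAULT_MAJORITY,
                  k: int = DEFAULT_K,
                  shell_only_votes: bool = False) -> LocusResult:
    """Search, assign, call the type, and (optionally) rank closest types."""
    hits = search(library, records, threshold=threshold)
    assignments = assign_best(records, hits, library)
    tc = call_type(assignments, majority=majority, shell_only=shell_only_votes)
    fingerprint = None
    closest = None
    if any(a.role is not Role.NONE for a in assignments):
        fingerprint = make_fingerprint(assignments, getattr(records[0], "id", "locus"))
        if registry is not None and len(registry) > 0:
            closest = rank_closest(fingerprint, registry, k=k, alpha=alpha)
    return LocusResult(assignments=assignments, type_call=tc,
                       fingerprint=fingerprint, closest=closest)


def evaluate_type_recovery(world: FixtureWorld, threshold: float | None = None,
                           alpha: float = DEFAULT_ALPHA,
                           majority: float = DEFAULT_MAJORITY) -> dict:
    """Train-on-half / classify-held-out benchmark on a fixture world.

    Profiles come from the first half of each family; the world's loci were
    assembled from the held-out halves.  Returns the fraction of loci whose
    majority call equals the true type with status assigned, and the
    fraction whose true type is ranked first against the truth-derived
    reference registry.
    """
    library = build_library(world, training_only=True)
    registry = make_registry(world)
    n = len(world.loci)
    if n == 0:
        raise EmptyResultError("world has no loci")
    correct = 0
    rank_first = 0
    for locus in world.loci:
        res = analyse_locus(locus.records, library, registry,
                            threshold=threshold, alpha=alpha, majority=majority)
        if res.type_call.status == "assigned" and \
                res.type_call.bmc_type == locus.true_type:
            correct += 1
        if res.closest and res.closest[0][0] == locus.true_type:
            rank_first += 1
    return {"n_loci": n, "accuracy": correct / n,
            "rank_first_fraction": rank_first / n}
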