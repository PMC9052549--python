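"""Best-hit assignment per protein and shell-only proteome scanning."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import BmcTyperError
from .profiles import Hit, ProfileLibrary, search
from .roles import (ROLE_COLORS, SHELL_ROLES, Role, classify_role)

__all__ = ["BestAssignment", "assign_best", "classify_role", "scan_shell_only",
           "Role", "ROLE_COLORS", "SHELL_ROLES", "assignment_table"]


@dataclass
class BestAssignment:
    """The single best-scoring profile for one protein (or none)."""

    query_id: str
    profile_name: str | None
    role: Role
    bmc_type: str | None
    bitscore: float | None
    is_shell: bool
    n_domains: int | None = None  # metadata from the winning hit

    @property
    def color(self) -> str:
        return ROLE_COLORS[self.role]


def _from_hit(hit: Hit, library: ProfileLibrary | None) -> BestAssignment:
    if library is not None and hit.profile_name in library.profiles:
        prof = library.profiles[hit.profile_name]
        role, bmc_type = prof.role, prof.bmc_type
        if bmc_type == "generic":
            bmc_type = None
    else:
        role, bmc_type = classify_role(hit.profile_name)
    return BestAssignment(query_id=hit.query_id, profile_name=hit.profile_name,
                          role=role, bmc_type=bmc_type, bitscore=hit.bitscore,
                          is_shell=role in SHELL_ROLES, n_domains=hit.n_domains)


def assign_best(records: Sequence, hits_per_record: Sequence[Sequence[Hit]],
                library: ProfileLibrary | None = None) -> list[BestAssignment]:
    """Reduce accepted hits to one assignment per protein.

    The hit with the maximal bitscore wins; exact ties break to the
    lexicographically smallest profile name, so the result is independent of
    hit order.  Proteins without hits get role NONE (grey).
    """
    if len(records) != len(hits_per_record):
        raise BmcTyperError(
            f"{len(records)} records but {len(hits_per_record)} hit lists")
    out: list[BestAssignment] = []
    for rec, hits in zip(records, hits_per_record):
        if not hits:
            out.append(BestAssignment(query_id=rec.id, profile_name=None,
                                      role=Role.NONE, bmc_type=None,
                                      bitscore=None, is_shell=False))
            continue
        best = min(hits, key=lambda h: (-h.bitscore, h.profile_name))
        out.append(_from_hit(best, library))
    return out


def scan_shell_only(records: Sequence, shell_library: ProfileLibrary,
                    threshold: float | None = None,
                    ) -> tuple[list[BestAssignment], dict[Role, int]]:
    """Scan a proteome with shell-protein profiles only.

    Returns the assignments of proteins with at least one accepted shell hit
    (in input order) and a count per shell class; counts for classes without
    hits are zero.  A library containing a non-shell profile is rejected.
    """
    for prof in shell_library:
        if prof.role not in SHELL_ROLES:
            raise BmcTyperError(
                f"shell-only scan received non-shell profile {prof.name!r} "
                f"(role {prof.role.value})")
    hits_per_record = search(shell_library, records, threshold=threshold)
    assignments = assign_best(records, hits_per_record, shell_library)
    shell_hits = [a for a in assignments if a.role is not Role.NONE]
    summary = {role: 0 for role in sorted(SHELL_ROLES, key=lambda r: r.name)}
    for a in shell_hits:
        summary[a.role] += 1
    return shell_hits, summary


def assignment_table(assignments: Sequence[BestAssignment]) -> str:
    """Render assignments as the tabular TSV report."""
    lines = ["query_id\tprofile_name\trole\tbmc_type\tbitscore\tis_shell"]
    for a in assignments:
        bits = "" if a.bitscore is None else f"{a.bitscore:.2f}"
        lines.append("\t".join([
            a.query_id, a.profile_name or "", a.role.value, a.bmc_type or "",
            bits, "yes" if a.is_shell else "no"]))
    return "\n".join(lines) + "\n"
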