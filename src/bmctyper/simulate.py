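"""Deterministic synthetic worlds: toy protein families, training MSAs,
profile libraries, and labeled BMC-like loci.

Every pipeline stage is testable without downloads.  A world is generated
from a single integer seed driving one numpy Generator stream, so
regeneration is bit-identical.  Each synthetic BMC type owns one
motif-anchored family per role (the six shell classes plus a signature
enzyme and an AldDh); family sequences share a fixed random motif with a
small per-position substitution noise between fixed-length random flanks,
so all members of a family have equal length and the raw family is its own
ungapped training alignment.  Loci sample a canonical role order with up to
two adjacent swaps and ~20% untyped bystander genes.  Family sequences are
split: the first half trains profiles, loci draw only from the held-out
half, so classification tests never see training sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alphabet import AMINO_ACIDS
from .errors import BmcTyperError
from .fingerprint import Fingerprint
from .locus import ProteinRecord
from .profiles import ProfileHMM, ProfileLibrary, build_profile
from .registry import TypeRegistry, TypeRegistryEntry
from .roles import Role, SHELL_ROLES, STEM_FOR_ROLE

#: family roles per synthetic type: all shell classes + signature enzyme + AldDh
FAMILY_ROLES = [Role.BMC_P, Role.BMC_H, Role.BMC_Hp, Role.BMC_Ts,
                Role.BMC_Tsp, Role.BMC_Tdp, Role.SIGNATURE_ENZYME, Role.ALDDH]

#: canonical gene order of a full synthetic locus (role stems)
CANONICAL_ORDER = [Role.SIGNATURE_ENZYME, Role.ALDDH, Role.BMC_H, Role.BMC_H,
                   Role.BMC_Hp, Role.BMC_Ts, Role.BMC_H, Role.BMC_Tsp,
                   Role.BMC_Tdp, Role.BMC_H, Role.BMC_P, Role.BMC_P,
                   Role.BMC_Ts, Role.BMC_H, Role.BMC_Hp, Role.BMC_P]

_COLORS = ["azure", "fuchsia", "amber", "coral", "jade", "ivory", "cobalt",
           "crimson", "saffron", "viridian", "umber", "celadon", "vermilion",
           "ochre", "periwinkle", "russet", "cerulean", "maroon",
           "chartreuse", "lavender"]

_AA = list(AMINO_ACIDS)


@dataclass
class Family:
    """One motif-anchored protein family of one (type, role)."""

    name: str
    type_label: str
    role: Role
    motif: str
    sequences: list[str]

    @property
    def training(self) -> list[str]:
        return self.sequences[:math.ceil(len(self.sequences) / 2)]

    @property
    def held_out(self) -> list[str]:
        return self.sequences[math.ceil(len(self.sequences) / 2):]


@dataclass
class FixtureLocus:
    locus_id: str
    true_type: str
    records: list[ProteinRecord]
    true_roles: list[Role]
    true_labels: list[str | None]  # family/profile name, None for bystanders

    def truth_fingerprint(self) -> Fingerprint:
        labels = [l for l in self.true_labels if l is not None]
        return Fingerprint(labels=labels, locus_id=self.locus_id)


@dataclass
class FixtureWorld:
    seed: int
    types: list[str]
    families: dict[tuple[str, Role], Family]
    loci: list[FixtureLocus]
    params: dict = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA) for _ in range(length))


def _mutate(rng: np.random.Generator, seq: str, noise: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < noise:
            out[i] = _AA[rng.integers(0, 20)]
    return "".join(out)


def generate_world(seed: int, n_types: int = 10, loci_per_type: int = 8,
                   locus_len: int = 20, n_seqs_per_family: int = 6,
                   motif_len: int = 28, flank_len: int = 8,
                   noise: float = 0.05, bystander_frac: float = 0.2,
                   ) -> FixtureWorld:
    """Generate a labeled fixture world; identical seeds give identical worlds."""
    if n_types < 2:
        raise BmcTyperError(f"need at least 2 types, got {n_types}")
    if loci_per_type < 1 or locus_len < 3:
        raise BmcTyperError("degenerate parameters: loci_per_type >= 1 and "
                            "locus_len >= 3 required")
    if n_seqs_per_family < 3:
        raise BmcTyperError("each family needs >= 3 sequences for a usable "
                            "training alignment")
    if not 0 <= noise <= 0.1:
        raise BmcTyperError(f"substitution noise must be in [0, 0.1], got {noise}")
    rng = np.random.default_rng(seed)
    types = [f"SYN{i + 1:02d}" for i in range(n_types)]
    families: dict[tuple[str, Role], Family] = {}
    fam_index = 0
    for t in types:
        for role in FAMILY_ROLES:
            color = _COLORS[fam_index % len(_COLORS)] + (
                "" if fam_index < len(_COLORS) else str(fam_index // len(_COLORS) + 1))
            name = f"{t}__{STEM_FOR_ROLE[role]}_{color}"
            motif = _random_seq(rng, motif_len)
            seqs = [
                _random_seq(rng, flank_len) + _mutate(rng, motif, noise)
                + _random_seq(rng, flank_len)
                for _ in range(n_seqs_per_family)
            ]
            families[(t, role)] = Family(name=name, type_label=t, role=role,
                                         motif=motif, sequences=seqs)
            fam_index += 1

    n_byst = round(bystander_frac * locus_len)
    core_len = locus_len - n_byst
    loci: list[FixtureLocus] = []
    for t in types:
        for k in range(loci_per_type):
            locus_id = f"{t}_L{k + 1}"
            roles = [CANONICAL_ORDER[i % len(CANONICAL_ORDER)]
                     for i in range(core_len)]
            if not any(r in SHELL_ROLES for r in roles):
                roles[-1] = Role.BMC_H
            # up to two seeded adjacent swaps
            for _ in range(int(rng.integers(0, 3))):
                if len(roles) > 1:
                    p = int(rng.integers(0, len(roles) - 1))
                    roles[p], roles[p + 1] = roles[p + 1], roles[p]
            genes: list[tuple[Role | None, str | None, str]] = []
            for role in roles:
                fam = families[(t, role)]
                seq = fam.held_out[int(rng.integers(0, len(fam.held_out)))]
                genes.append((role, fam.name, seq))
            for _ in range(n_byst):
                pos = int(rng.integers(0, len(genes) + 1))
                seq = _random_seq(rng, int(rng.integers(35, 61)))
                genes.insert(pos, (Role.NONE, None, seq))
            records = [ProteinRecord(id=f"{locus_id}_g{i + 1}", description="",
                                     index=i, seq=seq)
                       for i, (_, _, seq) in enumerate(genes)]
            loci.append(FixtureLocus(
                locus_id=locus_id, true_type=t, records=records,
                true_roles=[g[0] for g in genes],
                true_labels=[g[1] for g in genes]))
    return FixtureWorld(seed=seed, types=types, families=families, loci=loci,
                        params=dict(n_types=n_types, loci_per_type=loci_per_type,
                                    locus_len=locus_len,
                                    n_seqs_per_family=n_seqs_per_family,
                                    motif_len=motif_len, flank_len=flank_len,
                                    noise=noise, bystander_frac=bystander_frac))


def build_library(world: FixtureWorld, shell_only: bool = False,
                  training_only: bool = True) -> ProfileLibrary:
    """Build the type-specific profile library from the world's families.

    With ``training_only`` (the default) profiles are trained on the first
    half of each family, leaving the held-out half — from which loci were
    assembled — unseen.
    """
    profiles: dict[str, ProfileHMM] = {}
    for (t, role), fam in sorted(world.families.items(),
                                 key=lambda kv: kv[1].name):
        if shell_only and role not in SHELL_ROLES:
            continue
        msa = fam.training if training_only else fam.sequences
        profiles[fam.name] = build_profile(msa, fam.name, role=role, bmc_type=t)
    return ProfileLibrary(profiles=profiles, mode="type_specific")


def make_registry(world: FixtureWorld, include_sequences: bool = False,
                  ) -> TypeRegistry:
    """Reference registry with one truth example fingerprint per type."""
    entries: dict[str, TypeRegistryEntry] = {}
    for t in world.types:
        first = next(l for l in world.loci if l.true_type == t)
        components = sorted(fam.name for (tt, _), fam in world.families.items()
                            if tt == t)
        sequences: dict[str, str] = {}
        if include_sequences:
            for (tt, _), fam in sorted(world.families.items(),
                                       key=lambda kv: kv[1].name):
                if tt == t:
                    for i, seq in enumerate(fam.sequences):
                        sequences[f"{fam.name}_{i + 1}"] = seq
        entries[t] = TypeRegistryEntry(
            type_id=t, description=f"synthetic fixture type {t}",
            example_fingerprints=[first.truth_fingerprint()],
            component_inventory=components, sequences=sequences)
    return TypeRegistry(entries=entries)


def corrupt_locus(world: FixtureWorld, locus: FixtureLocus, mode: str,
                  seed: int) -> FixtureLocus:
    """Deterministically corrupt a fixture locus.

    * ``shuffle``: permute gene order (vote table unchanged);
    * ``mix_types``: replace half the shell genes (rounded up) and the typed
      enzyme genes with same-role counterparts from the other types, donors
      cycling, so no single type keeps a majority of the votes;
    * ``drop_shell``: remove every shell gene.
    """
    rng = np.random.default_rng(seed)
    genes = list(zip(locus.true_roles, locus.true_labels,
                     [r.seq for r in locus.records]))
    if mode == "shuffle":
        perm = rng.permutation(len(genes))
        genes = [genes[i] for i in perm]
    elif mode == "drop_shell":
        genes = [g for g in genes if g[0] not in SHELL_ROLES]
    elif mode == "mix_types":
        donors = [t for t in world.types if t != locus.true_type]
        shell_pos = [i for i, g in enumerate(genes) if g[0] in SHELL_ROLES]
        enzyme_pos = [i for i, g in enumerate(genes)
                      if g[0] not in SHELL_ROLES and g[1] is not None]
        n_shell_replace = math.ceil(len(shell_pos) / 2)
        chosen = sorted(rng.choice(shell_pos, size=n_shell_replace,
                                   replace=False).tolist()) + enzyme_pos
        for c, pos in enumerate(sorted(chosen)):
            role = genes[pos][0]
            donor = donors[c % len(donors)]
            fam = world.families[(donor, role)]
            seq = fam.held_out[int(rng.integers(0, len(fam.held_out)))]
            genes[pos] = (role, fam.name, seq)
    else:
        raise BmcTyperError(f"unknown corruption mode {mode!r}")
    records = [ProteinRecord(id=f"{locus.locus_id}_{mode}_g{i + 1}",
                             description="", index=i, seq=seq)
               for i, (_, _, seq) in enumerate(genes)]
    return FixtureLocus(locus_id=f"{locus.locus_id}_{mode}",
                        true_type=locus.true_type, records=records,
                        true_roles=[g[0] for g in genes],
                        true_labels=[g[1] for g in genes])


def write_world(world: FixtureWorld, outdir) -> None:
    """Write a world to disk: per-locus FASTA, truth TSV, training MSAs,
    registry file, and serialized profile library."""
    import os

    from .locus import write_multifasta
    from .profiles import save_library
    from .registry import save_registry

    os.makedirs(outdir, exist_ok=True)
    os.makedirs(os.path.join(outdir, "loci"), exist_ok=True)
    os.makedirs(os.path.join(outdir, "msas"), exist_ok=True)
    truth = ["locus_id\ttrue_type\tgene\trole\tprofile"]
    for locus in world.loci:
        write_multifasta(locus.records,
                         os.path.join(outdir, "loci", f"{locus.locus_id}.faa"))
        for rec, role, label in zip(locus.records, locus.true_roles,
                                    locus.true_labels):
            truth.append(f"{locus.locus_id}\t{locus.true_type}\t{rec.id}"
                         f"\t{role.value}\t{label or ''}")
    with open(os.path.join(outdir, "truth.tsv"), "w") as fh:
        fh.write("\n".join(truth) + "\n")
    for fam in sorted(world.families.values(), key=lambda f: f.name):
        recs = [ProteinRecord(id=f"{fam.name}_{i + 1}", description="",
                              index=i, seq=s)
                for i, s in enumerate(fam.training)]
        write_multifasta(recs, os.path.join(outdir, "msas", f"{fam.name}.afa"))
    save_registry(make_registry(world), os.path.join(outdir, "registry.tsv"))
    save_library(build_library(world), os.path.join(outdir, "library.txt"))
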