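"""Functional roles of BMC locus gene products and their display colors.

BMC shells are built from pfam00936 hexamers (BMC-H, plus the circularly
permuted BMC-H^p and the tandem-domain trimers BMC-T^s / BMC-T^sp / BMC-T^dp)
capped by pfam03319 pentamers (BMC-P).  Around the shell, a locus typically
encodes the signature enzyme that generates the aldehyde intermediate, the
core metabolosome enzymes (AldDh, AlcDh, PTAC), and regulators.

Profiles are named ``<ROLE>_<color>`` (e.g. ``H_azure``) or, for BMC-type
specific profiles trained on sequences of a single type,
``<TYPE>__<ROLE>_<color>`` (e.g. ``SPU1__H_azure``); ``__`` is the reserved
type separator.
"""

from __future__ import annotations

import enum


class Role(enum.Enum):
    BMC_P = "BMC-P"
    BMC_H = "BMC-H"
    BMC_Hp = "BMC-Hp"
    BMC_Ts = "BMC-Ts"
    BMC_Tsp = "BMC-Tsp"
    BMC_Tdp = "BMC-Tdp"
    SIGNATURE_ENZYME = "signature_enzyme"
    REGULATOR = "regulator"
    ALDDH = "AldDh"
    ALCDH = "AlcDh"
    PTAC = "PTAC"
    OTHER_CONSERVED = "other_conserved"
    NONE = "none"


#: shell-forming roles (pfam00936 / pfam03319 families)
SHELL_ROLES = frozenset(
    {Role.BMC_P, Role.BMC_H, Role.BMC_Hp, Role.BMC_Ts, Role.BMC_Tsp, Role.BMC_Tdp}
)

#: fixed display color per role (SVG color keywords)
ROLE_COLORS = {
    Role.BMC_P: "yellow",
    Role.BMC_H: "blue",
    Role.BMC_Hp: "blue",
    Role.BMC_Ts: "lightblue",
    Role.BMC_Tsp: "lightblue",
    Role.BMC_Tdp: "teal",
    Role.SIGNATURE_ENZYME: "purple",
    Role.REGULATOR: "orange",
    Role.ALDDH: "red",
    Role.ALCDH: "green",
    Role.PTAC: "magenta",
    Role.OTHER_CONSERVED: "black",
    Role.NONE: "grey",
}

#: name-stem -> role, for parsing profile names
ROLE_STEMS = {
    "P": Role.BMC_P,
    "H": Role.BMC_H,
    "Hp": Role.BMC_Hp,
    "Ts": Role.BMC_Ts,
    "Tsp": Role.BMC_Tsp,
    "Tdp": Role.BMC_Tdp,
    "SIG": Role.SIGNATURE_ENZYME,
    "REG": Role.REGULATOR,
    "ALDDH": Role.ALDDH,
    "ALCDH": Role.ALCDH,
    "PTAC": Role.PTAC,
}

STEM_FOR_ROLE = {role: stem for stem, role in ROLE_STEMS.items()}

TYPE_SEPARATOR = "__"


def classify_role(profile_name: str) -> tuple[Role, str | None]:
    """Parse a profile name into (role, bmc_type).

    ``"SPU1__H_azure"`` -> (BMC_H, "SPU1"); ``"P_amber"`` -> (BMC_P, None).
    Names that do not follow the convention map to OTHER_CONSERVED with no
    type.
    """
    bmc_type: str | None = None
    stem_part = profile_name
    if TYPE_SEPARATOR in profile_name:
        prefix, stem_part = profile_name.split(TYPE_SEPARATOR, 1)
        if prefix:
            bmc_type = prefix
    stem = stem_part.split("_", 1)[0]
    role = ROLE_STEMS.get(stem)
    if role is None:
        return Role.OTHER_CONSERVED, bmc_type
    return role, bmc_type
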