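"""The 20-letter amino-acid alphabet and sequence encoding.

Column order matches the HMMER convention (alphabetical one-letter codes).
Non-standard residues (B, J, O, U, X, Z and anything else) are mapped to a
sentinel 21st column that every emission table — including the null model —
fills with the flat background probability 1/20, so such positions contribute
zero bits to any score.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
N_AA = 20
#: index of the sentinel column used for non-standard residues
UNKNOWN = N_AA

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

GAP_CHARS = frozenset("-.")


def uniform_background() -> np.ndarray:
    """Flat background distribution over the 20 standard amino acids."""
    return np.full(N_AA, 1.0 / N_AA)


def encode(seq: str) -> np.ndarray:
    """Encode a protein string as int64 indices; unknown letters -> UNKNOWN."""
    return np.array([AA_INDEX.get(c, UNKNOWN) for c in seq.upper()], dtype=np.int64)


def with_unknown_column(vec: np.ndarray) -> np.ndarray:
    """Append the 1/20 sentinel column to a length-20 probability vector."""
    out = np.empty(N_AA + 1)
    out[:N_AA] = vec
    out[UNKNOWN] = 1.0 / N_AA
    return out
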