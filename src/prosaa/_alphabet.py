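"""Amino-acid alphabet constants and the GBMR4 reduced alphabet.

The canonical residue ordering is the one used by HMMER3 ASCII model files
(alphabetical one-letter codes). 'X' is tolerated in reads but is opaque: it
belongs to its own reduced class, never matches a seed k-gram, and counts as a
mismatch in overlap and mapping comparisons.
"""

from __future__ import annotations

import numpy as np

#: HMMER3 amino alphabet ordering.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

AA_TO_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

N_AA = 20

# GBMR4 reduced alphabet: glycine and proline alone, the remaining residues
# split into a small/polar and a large/hydrophobic class. 'X' gets class 4,
# which never occurs in a model-consensus key.
_GBMR4_CLASSES = ("G", "P", "ADKERNTSQ", "YFLIVMCWH")

GBMR4 = {}
for _ci, _members in enumerate(_GBMR4_CLASSES):
    for _a in _members:
        GBMR4[_a] = _ci
GBMR4["X"] = 4


def encode(seq: str) -> np.ndarray:
    """Encode a peptide string as int8 indices; 'X' (or unknown) becomes -1."""
    return np.array([AA_TO_INDEX.get(c, -1) for c in seq], dtype=np.int8)


def reduce_gbmr4(seq: str) -> str:
    """Map a peptide string to its GBMR4 class string (digits '0'..'4')."""
    return "".join(str(GBMR4.get(c, 4)) for c in seq)


def is_valid_peptide(seq: str) -> bool:
    return all(c in AA_TO_INDEX or c == "X" for c in seq)
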