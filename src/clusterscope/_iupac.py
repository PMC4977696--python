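"""IUPAC nucleotide code tables shared across modules.

Base sets are represented both as frozensets (readable) and as 4-bit masks
(A=1, C=2, G=4, T=8) for vectorised column classification.  ``U`` is treated
as ``T``.  The gap character ``-`` is deliberately absent: gaps are handled
structurally, never as a residue.
"""

from __future__ import annotations

import numpy as np

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

NUCLEOTIDE_LETTERS = frozenset(IUPAC_SETS)

#: Codes standing for more than one base.
AMBIGUITY_CODES = frozenset(c for c, s in IUPAC_SETS.items() if len(s) > 1)

#: Two-base ambiguity codes containing a given concrete base; used by the
#: synthetic-data generator to inject *compatible* ambiguities.
AMBIGUITY_FOR_BASE: dict[str, list[str]] = {
    "A": ["R", "W", "M"],
    "C": ["Y", "S", "M"],
    "G": ["R", "S", "K"],
    "T": ["Y", "W", "K"],
}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "U": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B", "N": "N", "-": "-",
}
_COMPLEMENT_TABLE = str.maketrans(_COMPLEMENT)

_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}

#: byte -> 4-bit base-set mask; 0 for any byte that is not an IUPAC code.
MASK_TABLE = np.zeros(256, dtype=np.uint8)
for _code, _bases in IUPAC_SETS.items():
    MASK_TABLE[ord(_code)] = sum(_BASE_BIT[b] for b in _bases)

#: byte -> True when the byte is a code for >1 base.
AMBIG_TABLE = np.zeros(256, dtype=bool)
for _code in AMBIGUITY_CODES:
    AMBIG_TABLE[ord(_code)] = True


def reverse_complement(seq: str) -> str:
    """Reverse-complement a nucleotide string, mapping IUPAC codes correctly."""
    return seq.translate(_COMPLEMENT_TABLE)[::-1]


def is_compatible(x: str, y: str) -> bool:
    """True when the base sets of two IUPAC codes intersect."""
    return bool(IUPAC_SETS[x] & IUPAC_SETS[y])
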