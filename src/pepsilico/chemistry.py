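"""Elemental composition of the 20 peptide-bonded residues.

Single source of truth for element counts (C, H, N, O, S) and monoisotopic
element masses, shared by the mass and drug-likeness descriptor modules so
the two mass routes (residue-mass summation vs molecular-formula summation)
agree to machine precision.
"""

from __future__ import annotations

ELEMENT_SYMBOLS = ("C", "H", "N", "O", "S")

ELEMENT_MONO_MASS = {
    "C": 12.0, "H": 1.0078250319, "N": 14.0030740052,
    "O": 15.9949146221, "S": 31.97207069,
}

# Peptide-bonded residue (= amino acid minus water) element counts.
RESIDUE_ELEMENTS: dict[str, tuple[int, int, int, int, int]] = {
    "G": (2, 3, 1, 1, 0), "A": (3, 5, 1, 1, 0), "S": (3, 5, 1, 2, 0),
    "P": (5, 7, 1, 1, 0), "V": (5, 9, 1, 1, 0), "T": (4, 7, 1, 2, 0),
    "C": (3, 5, 1, 1, 1), "L": (6, 11, 1, 1, 0), "I": (6, 11, 1, 1, 0),
    "N": (4, 6, 2, 2, 0), "D": (4, 5, 1, 3, 0), "Q": (5, 8, 2, 2, 0),
    "K": (6, 12, 2, 1, 0), "E": (5, 7, 1, 3, 0), "M": (5, 9, 1, 1, 1),
    "H": (6, 7, 3, 1, 0), "F": (9, 9, 1, 1, 0), "R": (6, 12, 4, 1, 0),
    "Y": (9, 9, 1, 2, 0), "W": (11, 10, 2, 1, 0),
}
WATER_ELEMENTS = (0, 2, 0, 1, 0)


def _mass(counts: tuple[int, int, int, int, int]) -> float:
    return sum(n * ELEMENT_MONO_MASS[sym] for sym, n in zip(ELEMENT_SYMBOLS, counts))


#: Monoisotopic residue masses derived from the elemental compositions.
RESIDUE_MONO_MASS = {aa: _mass(counts) for aa, counts in RESIDUE_ELEMENTS.items()}
WATER_MONO_MASS = _mass(WATER_ELEMENTS)
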