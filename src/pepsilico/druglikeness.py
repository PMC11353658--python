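"""Sequence-derived drug-likeness descriptors for linear peptides.

Everything here is computed from residue templates encoding standard
peptide chemistry (peptide-bonded residue = amino acid minus water; the
chain adds one water back), so molecular formula, monoisotopic mass,
hydrogen-bond acceptor/donor counts and a topological polar surface area
follow from the sequence alone:

* HBA - Lipinski convention: total nitrogen + oxygen atoms.
* HBD - Lipinski convention: hydrogens bonded to N or O. The backbone
  contributes one amide H per non-proline residue (none for proline, a
  secondary amine), the N-terminus two amine hydrogens (one for proline)
  and the C-terminal carboxyl one.
* TPSA - Ertl fragment additivity with per-residue contributions resolved
  by terminus context (sulfur contributes nothing, as in the original
  parameterization).
* logP - a transparent additive estimate: Fauchere-Pliska side-chain
  hydrophobicity plus fixed backbone and termini increments. It deliberately
  does NOT reproduce machine-learned partition coefficients; it exists to
  place peptides on the logP <= 5 side of the rule-of-five ledger, where
  every unmodified oligopeptide sits comfortably.

Rule-of-five evaluation supports the classic four-criterion mode
(MW <= 500, HBA <= 10, HBD <= 5, logP <= 5) and an extended five-criterion
mode adding TPSA <= 140 A^2. All limits are inclusive.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .chemistry import (
    ELEMENT_MONO_MASS,
    ELEMENT_SYMBOLS,
    RESIDUE_ELEMENTS,
    WATER_ELEMENTS,
)
from .io_formats import validate_sequence

# Side-chain hydrogens on N or O (Lipinski donors; thiol S-H is excluded).
SIDECHAIN_DONOR_H = {
    "S": 1, "T": 1, "Y": 1, "N": 2, "Q": 2, "D": 1, "E": 1,
    "K": 2, "R": 4, "H": 1, "W": 1,
}

# Ertl fragment TPSA contributions (A^2). Backbone: amide N-H 12.03,
# tertiary (proline) amide N 3.24, N-terminal primary amine 26.02
# (secondary, proline, 12.03), carbonyl O 17.07, C-terminal COOH 37.30.
_TPSA_AMIDE_NH = 12.03
_TPSA_N_TERTIARY = 3.24
_TPSA_NTERM_NH2 = 26.02
_TPSA_NTERM_PRO = 12.03
_TPSA_CARBONYL_O = 17.07
_TPSA_COOH = 37.30
SIDECHAIN_TPSA = {
    "S": 20.23, "T": 20.23, "Y": 20.23, "D": 37.30, "E": 37.30,
    "N": 43.09, "Q": 43.09, "K": 26.02, "R": 61.90, "H": 28.68, "W": 15.79,
}

# Fauchere-Pliska side-chain octanol/water hydrophobicity (pi values).
SIDECHAIN_PI = {
    "A": 0.31, "R": -1.01, "N": -0.60, "D": -0.77, "C": 1.54, "Q": -0.22,
    "E": -0.64, "G": 0.00, "H": 0.13, "I": 1.80, "L": 1.70, "K": -0.99,
    "M": 1.23, "F": 1.79, "P": 0.72, "S": -0.04, "T": 0.26, "W": 2.25,
    "Y": 0.96, "V": 1.22,
}
# Hydrophilicity increments for the peptide backbone unit and the charged termini.
_LOGP_BACKBONE_PER_RESIDUE = -0.90
_LOGP_TERMINI = -1.00

RO5_LIMITS = {"mw": 500.0, "hba": 10, "hbd": 5, "logp": 5.0, "tpsa": 140.0}


@dataclass(frozen=True)
class PeptideDescriptors:
    sequence: str
    formula: str
    mw_monoisotopic: float
    hba: int
    hbd: int
    logp_estimate: float
    tpsa_estimate: float
    ro5_flags: dict[str, bool]
    ro5_violations: int


def molecular_formula(sequence: str) -> Counter:
    """Element counts of the peptide: residue templates plus one water."""
    validate_sequence(sequence)
    counts = Counter(dict(zip(ELEMENT_SYMBOLS, WATER_ELEMENTS)))
    for aa in sequence:
        for sym, n in zip(ELEMENT_SYMBOLS, RESIDUE_ELEMENTS[aa]):
            counts[sym] += n
    return counts


def formula_string(counts: Counter) -> str:
    """Hill-order-ish formula string (C, H, then alphabetical), e.g. C18H28N4O6."""
    parts = []
    for sym in ELEMENT_SYMBOLS:
        n = counts.get(sym, 0)
        if n == 1:
            parts.append(sym)
        elif n > 1:
            parts.append(f"{sym}{n}")
    return "".join(parts)


def monoisotopic_mass_from_formula(counts: Counter) -> float:
    return sum(ELEMENT_MONO_MASS[sym] * n for sym, n in counts.items())


def hba_count(sequence: str) -> int:
    """Lipinski hydrogen-bond acceptors: total N + O atoms."""
    counts = molecular_formula(sequence)
    return counts["N"] + counts["O"]


def hbd_count(sequence: str) -> int:
    """Lipinski hydrogen-bond donors: hydrogens bonded to N or O."""
    validate_sequence(sequence)
    total = 1  # C-terminal carboxyl OH
    for i, aa in enumerate(sequence):
        if i == 0:
            total += 1 if aa == "P" else 2  # N-terminal amine
        else:
            total += 0 if aa == "P" else 1  # backbone amide H
        total += SIDECHAIN_DONOR_H.get(aa, 0)
    return total


def logp_estimate(sequence: str) -> float:
    """Additive octanol/water partition estimate (see module docstring)."""
    validate_sequence(sequence)
    side = sum(SIDECHAIN_PI[aa] for aa in sequence)
    return side + _LOGP_BACKBONE_PER_RESIDUE * len(sequence) + _LOGP_TERMINI


def tpsa_estimate(sequence: str) -> float:
    """Ertl-additive topological polar surface area (A^2)."""
    validate_sequence(sequence)
    total = 0.0
    last = len(sequence) - 1
    for i, aa in enumerate(sequence):
        if i == 0:
            total += _TPSA_NTERM_PRO if aa == "P" else _TPSA_NTERM_NH2
        else:
            total += _TPSA_N_TERTIARY if aa == "P" else _TPSA_AMIDE_NH
        total += _TPSA_COOH if i == last else _TPSA_CARBONYL_O
        total += SIDECHAIN_TPSA.get(aa, 0.0)
    return round(total, 10)


def ro5_violations(
    descriptors: PeptideDescriptors | None = None,
    mode: str = "lipinski4",
    *,
    mw: float | None = None,
    hba: int | None = None,
    hbd: int | None = None,
    logp: float | None = None,
    tpsa: float | None = None,
) -> tuple[int, dict[str, bool]]:
    """Count rule-of-five violations; flags are True where the rule is met.

    ``lipinski4`` checks MW, HBA, HBD and logP; ``extended5`` adds TPSA.
    All limits are inclusive (a descriptor exactly at its limit complies).
    """
    if descriptors is not None:
        mw = descriptors.mw_monoisotopic
        hba = descriptors.hba
        hbd = descriptors.hbd
        logp = descriptors.logp_estimate
        tpsa = descriptors.tpsa_estimate
    flags = {
        "mw": mw <= RO5_LIMITS["mw"],
        "hba": hba <= RO5_LIMITS["hba"],
        "hbd": hbd <= RO5_LIMITS["hbd"],
        "logp": logp <= RO5_LIMITS["logp"],
    }
    if mode == "extended5":
        flags["tpsa"] = tpsa <= RO5_LIMITS["tpsa"]
    elif mode != "lipinski4":
        raise ValueError(f"unknown RO5 mode '{mode}'")
    return sum(not ok for ok in flags.values()), flags


def peptide_descriptors(sequence: str, mode: str = "lipinski4") -> PeptideDescriptors:
    """All drug-likeness descriptors for one peptide sequence."""
    counts = molecular_formula(sequence)
    mw = monoisotopic_mass_from_formula(counts)
    hba = counts["N"] + counts["O"]
    hbd = hbd_count(sequence)
    logp = logp_estimate(sequence)
    tpsa = tpsa_estimate(sequence)
    violations, flags = ro5_violations(
        mode=mode, mw=mw, hba=hba, hbd=hbd, logp=logp, tpsa=tpsa
    )
    return PeptideDescriptors(
        sequence=sequence, formula=formula_string(counts), mw_monoisotopic=mw,
        hba=hba, hbd=hbd, logp_estimate=logp, tpsa_estimate=tpsa,
        ro5_flags=flags, ro5_violations=violations,
    )
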