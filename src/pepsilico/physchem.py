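"""ProtParam-style physicochemical descriptors for proteins and peptides.

Implements the classic sequence-only descriptors: molecular weight (average
and monoisotopic), charged-residue counts, theoretical isoelectric point,
GRAVY (grand average of hydropathy, Kyte-Doolittle), aliphatic index
(Ikai), instability index (Guruprasad dipeptide weights), molar extinction
coefficient (Gill-von Hippel), an N-terminal half-life lookup and the
five-class amino-acid composition (negative / positive / non-polar / polar /
aromatic) used when characterizing muscle-protein substrates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio.SeqUtils.ProtParamData import DIWV  # published Guruprasad dipeptide weights

from .chemistry import RESIDUE_MONO_MASS, WATER_MONO_MASS
from .io_formats import validate_sequence

# --- residue mass tables (Da) -------------------------------------------------
# Standard residue (= amino acid minus water) masses; one water is added per
# chain. Monoisotopic masses are derived from elemental compositions so the
# formula-based route reproduces them exactly.

MONOISOTOPIC_MASS = RESIDUE_MONO_MASS
AVERAGE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MONO = WATER_MONO_MASS
WATER_AVG = 18.01524

# Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# pKa sets for the titration model. "bjellqvist" is the set used by the
# classic web tool (N-terminal pKa depends on the first residue); "emboss"
# is the single-valued alternative. Side chains: D, E, C, Y acidic; H, K, R basic.
PKA_SETS: dict[str, dict[str, float | dict[str, float]]] = {
    "bjellqvist": {
        "c_term": 3.55,
        "n_term_default": 7.5,
        "n_term_by_residue": {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36,
                              "T": 6.82, "V": 7.44, "E": 7.7},
        "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0, "H": 5.98, "K": 10.0, "R": 12.0,
    },
    "emboss": {
        "c_term": 3.6,
        "n_term_default": 8.6,
        "n_term_by_residue": {},
        "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1, "H": 6.5, "K": 10.8, "R": 12.5,
    },
}

# Five-class grouping used for amino-acid distribution profiles.
AA_CLASSES = {
    "negative": set("ED"),
    "positive": set("KR"),
    "non_polar": set("VPMLIGA"),
    "polar": set("TSQNHC"),
    "aromatic": set("YWF"),
}

# N-end-rule half-life lookup (mammalian reticulocytes in vitro, yeast and
# E. coli in vivo), indexed by the N-terminal residue.
HALF_LIFE = {
    "A": ("4.4 hour", "20 min", ">10 hour"),
    "R": ("1 hour", "2 min", "2 min"),
    "N": ("1.4 hour", "3 min", ">10 hour"),
    "D": ("1.1 hour", "3 min", ">10 hour"),
    "C": ("1.2 hour", ">20 hour", ">10 hour"),
    "Q": ("0.8 hour", "10 min", ">10 hour"),
    "E": ("1 hour", "30 min", ">10 hour"),
    "G": ("30 hour", ">20 hour", ">10 hour"),
    "H": ("3.5 hour", "10 min", ">10 hour"),
    "I": ("20 hour", "30 min", ">10 hour"),
    "L": ("5.5 hour", "3 min", "2 min"),
    "K": ("1.3 hour", "3 min", "2 min"),
    "M": ("30 hour", ">20 hour", ">10 hour"),
    "F": ("1.1 hour", "3 min", "2 min"),
    "P": (">20 hour", ">20 hour", "?"),
    "S": ("1.9 hour", ">20 hour", ">10 hour"),
    "T": ("7.2 hour", ">20 hour", ">10 hour"),
    "W": ("2.8 hour", "3 min", "2 min"),
    "Y": ("2.8 hour", "10 min", "2 min"),
    "V": ("100 hour", ">20 hour", ">10 hour"),
}


@dataclass(frozen=True)
class PhyschemReport:
    id: str
    length: int
    mw_average: float
    mw_monoisotopic: float
    neg_residues: int
    pos_residues: int
    pi: float
    gravy: float
    aliphatic_index: float
    instability_index: float
    stability_class: str
    extinction_oxidized: int
    extinction_reduced: int
    aa_class_distribution: dict[str, float]
    half_life_mammalian: str


def molecular_weight(sequence: str, mode: str = "average") -> float:
    """Chain mass in Da: sum of residue masses plus one water."""
    validate_sequence(sequence)
    if mode == "average":
        table, water = AVERAGE_MASS, WATER_AVG
    elif mode == "monoisotopic":
        table, water = MONOISOTOPIC_MASS, WATER_MONO
    else:
        raise ValueError(f"unknown mass mode '{mode}'")
    return sum(table[aa] for aa in sequence) + water


def gravy(sequence: str) -> float:
    """Mean Kyte-Doolittle hydropathy per residue."""
    validate_sequence(sequence)
    return sum(KYTE_DOOLITTLE[aa] for aa in sequence) / len(sequence)


def aliphatic_index(sequence: str) -> float:
    """Ikai's aliphatic index: X(Ala) + 2.9 X(Val) + 3.9 (X(Ile) + X(Leu)).

    X are mole-percentages; the index estimates the relative volume occupied
    by aliphatic side chains, a correlate of thermostability.
    """
    validate_sequence(sequence)
    n = len(sequence)
    x = {aa: 100.0 * sequence.count(aa) / n for aa in "AVIL"}
    return x["A"] + 2.9 * x["V"] + 3.9 * (x["I"] + x["L"])


def instability_index(sequence: str) -> float:
    """Guruprasad instability index: (10/L) x sum of dipeptide weights."""
    validate_sequence(sequence)
    if len(sequence) < 2:
        raise ValueError("instability index requires at least 2 residues")
    total = sum(DIWV[a][b] for a, b in zip(sequence[:-1], sequence[1:]))
    return 10.0 / len(sequence) * total


def stability_class(ii: float) -> str:
    """'unstable' iff the instability index exceeds 40 (strict)."""
    return "unstable" if ii > 40.0 else "stable"


def net_charge(sequence: str, ph: float, pka_set: str = "bjellqvist") -> float:
    """Henderson-Hasselbalch net charge at ``ph`` (termini + ionizable side chains)."""
    validate_sequence(sequence)
    pka = PKA_SETS[pka_set]
    nt = pka["n_term_by_residue"].get(sequence[0], pka["n_term_default"])

    def pos(p: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (ph - p))

    def neg(p: float) -> float:
        return -1.0 / (1.0 + 10.0 ** (p - ph))

    charge = pos(nt) + neg(pka["c_term"])
    for aa in sequence:
        if aa in ("H", "K", "R"):
            charge += pos(pka[aa])
        elif aa in ("D", "E", "C", "Y"):
            charge += neg(pka[aa])
    return charge


def isoelectric_point(
    sequence: str, pka_set: str = "bjellqvist", tol: float = 1e-4
) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    The titration function is strictly decreasing in pH, so bisection always
    converges; iteration stops when |charge| < ``tol``.
    """
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        q = net_charge(sequence, mid, pka_set=pka_set)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def charged_residue_counts(sequence: str) -> tuple[int, int]:
    """(negative D+E count, positive K+R count)."""
    validate_sequence(sequence)
    neg = sum(sequence.count(aa) for aa in "DE")
    pos = sum(sequence.count(aa) for aa in "KR")
    return neg, pos


def extinction_coefficient(sequence: str, cystines: str = "oxidized") -> int:
    """Gill-von Hippel molar extinction coefficient at 280 nm (M^-1 cm^-1).

    5500 per Trp + 1490 per Tyr; oxidized mode adds 125 per cystine pair
    (floor(nCys / 2)), reduced mode counts no cystines.
    """
    validate_sequence(sequence)
    n_w, n_y, n_c = sequence.count("W"), sequence.count("Y"), sequence.count("C")
    value = 5500 * n_w + 1490 * n_y
    if cystines == "oxidized":
        value += 125 * (n_c // 2)
    elif cystines != "reduced":
        raise ValueError(f"unknown cystine mode '{cystines}'")
    return value


def aa_class_distribution(sequence: str) -> dict[str, float]:
    """Fractions over the five classes; all 20 residues are covered, so they sum to 1."""
    validate_sequence(sequence)
    n = len(sequence)
    return {
        cls: sum(1 for aa in sequence if aa in members) / n
        for cls, members in AA_CLASSES.items()
    }


def half_life(sequence: str, organism: str = "mammalian") -> str:
    """Estimated half-life from the N-terminal residue (static N-end-rule lookup)."""
    validate_sequence(sequence)
    idx = {"mammalian": 0, "yeast": 1, "ecoli": 2}
    try:
        return HALF_LIFE[sequence[0]][idx[organism]]
    except KeyError:
        raise ValueError(f"unknown organism '{organism}'") from None


def physchem_report(record_id: str, sequence: str, pka_set: str = "bjellqvist") -> PhyschemReport:
    """All descriptors for one sequence (requires length >= 2 for the instability index)."""
    neg, pos = charged_residue_counts(sequence)
    ii = instability_index(sequence)
    return PhyschemReport(
        id=record_id,
        length=len(sequence),
        mw_average=molecular_weight(sequence, "average"),
        mw_monoisotopic=molecular_weight(sequence, "monoisotopic"),
        neg_residues=neg,
        pos_residues=pos,
        pi=isoelectric_point(sequence, pka_set=pka_set),
        gravy=gravy(sequence),
        aliphatic_index=aliphatic_index(sequence),
        instability_index=ii,
        stability_class=stability_class(ii),
        extinction_oxidized=extinction_coefficient(sequence, "oxidized"),
        extinction_reduced=extinction_coefficient(sequence, "reduced"),
        aa_class_distribution=aa_class_distribution(sequence),
        half_life_mammalian=half_life(sequence),
    )


def fetch_uniprot_fasta(accession: str, timeout: float = 10.0) -> str:
    """Fetch one sequence from UniProt's REST endpoint (network required).

    Returns the raw sequence string. Used only by optional comparisons
    against published reference values; never by the core pipeline.
    """
    from urllib.request import urlopen

    url = f"https://rest.uniprot.org/uniprotkb/{accession}.fasta"
    with urlopen(url, timeout=timeout) as fh:  # noqa: S310 - fixed https host
        text = fh.read().decode()
    lines = [ln.strip() for ln in text.splitlines() if ln and not ln.startswith(">")]
    sequence = "".join(lines).upper()
    validate_sequence(sequence, record_id=accession)
    return sequence
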