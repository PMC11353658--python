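"""Generators for every input the pipeline needs, with known ground truth.

Three kinds of synthetic input are produced deterministically from a seed:

* random protein sequences with a controlled amino-acid composition
  (defaults emulate a small muscle-protein panel: a handful of proteins a
  few hundred residues long);
* small bioactivity motif databases (fragment, activity) for exercising the
  release-frequency statistics;
* toy two-chain complexes laid out on a rigid grid so that exactly the
  requested residue pairs sit within contact distance - the generator
  declares its own interfacial-contact ground truth by construction, which
  the geometric contact counter must then reproduce.

The module also carries the twelve candidate peptides identified from
milkfish muscle hydrolysates together with their published screening scores
(general bioactivity and per-activity predictions); the scores are
annotations consumed by the screening step, never recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import CANONICAL_AA, BioactivityEntry, ProteinRecord

# One-letter -> 3-letter residue names (inverse of the parser's map).
ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# Rigid residue template: backbone N, CA, C, O plus one side-chain carbon,
# enough for heavy-atom contact logic without rotamer modelling.
_RESIDUE_TEMPLATE = (
    ("N", "N", (0.00, 1.45, 0.00)),
    ("CA", "C", (0.00, 0.00, 0.00)),
    ("C", "C", (1.52, 0.00, 0.00)),
    ("O", "O", (2.12, 1.05, 0.00)),
    ("CB", "C", (-0.75, -1.20, 0.40)),
)
_TEMPLATE_Y_MAX = 1.45
_TEMPLATE_Y_MIN = -1.20


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic study; the seed fixes every downstream byte."""

    seed: int = 0
    n_proteins: int = 9
    protein_length: int = 300
    aa_composition: dict[str, float] | None = None  # None = uniform
    motif_db_spec: list[tuple[str, str]] | None = None
    complex_n_residues: int = 8
    complex_n_contacts: int = 3
    complex_contact_separation: float = 6.0
    complex_far_separation: float = 18.0

    def composition_vector(self) -> np.ndarray:
        if self.aa_composition is None:
            return np.full(20, 1.0 / 20.0)
        vec = np.array([self.aa_composition.get(aa, 0.0) for aa in CANONICAL_AA])
        if abs(vec.sum() - 1.0) > 1e-9:
            raise ValueError("amino-acid composition must sum to 1")
        return vec


def generate_proteins(spec: SyntheticSpec) -> list[ProteinRecord]:
    """Deterministic random proteins whose composition converges to the spec."""
    rng = np.random.default_rng(spec.seed)
    probs = spec.composition_vector()
    alphabet = np.array(list(CANONICAL_AA))
    records = []
    for i in range(spec.n_proteins):
        seq = "".join(rng.choice(alphabet, size=spec.protein_length, p=probs))
        records.append(
            ProteinRecord(id=f"SYN{i + 1:03d}", sequence=seq,
                          description="synthetic protein")
        )
    return records


def generate_motif_db(
    spec: SyntheticSpec,
    activities: tuple[str, ...] = ("ACE inhibitor", "DPP IV inhibitor", "antioxidative"),
    n_fragments: int = 12,
    fragment_lengths: tuple[int, int] = (2, 4),
) -> list[BioactivityEntry]:
    """A small random motif database, or the explicit spec list when given."""
    if spec.motif_db_spec is not None:
        return [
            BioactivityEntry(fragment=frag, activity=act, source_id="spec")
            for frag, act in spec.motif_db_spec
        ]
    rng = np.random.default_rng(spec.seed + 1)
    alphabet = np.array(list(CANONICAL_AA))
    entries: list[BioactivityEntry] = []
    seen: set[tuple[str, str]] = set()
    while len(entries) < n_fragments:
        k = int(rng.integers(fragment_lengths[0], fragment_lengths[1] + 1))
        frag = "".join(rng.choice(alphabet, size=k))
        act = str(rng.choice(np.array(activities)))
        if (frag, act) in seen:
            continue
        seen.add((frag, act))
        entries.append(BioactivityEntry(fragment=frag, activity=act, source_id="synthetic"))
    return entries


@dataclass
class ToyComplexTruth:
    """Ground truth the toy-complex generator declares by construction."""

    n_atoms: int
    contact_pairs: list[tuple[tuple[str, str], tuple[str, str]]]
    ic_counts: dict[str, int] = field(default_factory=dict)
    residues_a: list[str] = field(default_factory=list)
    residues_b: list[str] = field(default_factory=list)


def _pdb_atom_line(serial: int, name: str, resname: str, chain: str,
                   resseq: int, x: float, y: float, z: float, element: str) -> str:
    padded = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {padded}{'':1s}{resname:>3s} {chain}{resseq:4d}"
        f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
    )


def generate_toy_complex(
    spec: SyntheticSpec,
    class_map: dict[str, str] | None = None,
) -> tuple[str, ToyComplexTruth]:
    """A two-chain PDB-format complex with hand-countable interfacial contacts.

    Chain A and chain B each carry ``complex_n_residues`` residues on a
    20-Angstrom grid; for exactly ``complex_n_contacts`` residue indices the
    two chains are brought to ``complex_contact_separation`` (inside the
    5.5-Angstrom heavy-atom contact cutoff, outside clash range), all other
    opposite pairs sit at ``complex_far_separation`` and every non-opposite
    pair is separated by the grid spacing. The returned ground truth lists
    the engineered contact pairs and their class-pair counts.
    """
    n = spec.complex_n_residues
    if spec.complex_n_contacts > n:
        raise ValueError("cannot engineer more contacts than residues")
    gap = spec.complex_contact_separation - (_TEMPLATE_Y_MAX - _TEMPLATE_Y_MIN)
    if gap <= 2.0:
        raise ValueError("contact separation would overlap atoms")

    rng = np.random.default_rng(spec.seed + 2)
    three = np.array(list(ONE_TO_THREE.values()))
    residues_a = [str(r) for r in rng.choice(three, size=n)]
    residues_b = [str(r) for r in rng.choice(three, size=n)]
    contact_idx = sorted(rng.choice(n, size=spec.complex_n_contacts, replace=False))

    spacing = 20.0
    lines = []
    serial = 0

    def place(chain: str, resname: str, resseq: int, origin: tuple[float, float, float],
              flip: bool) -> None:
        nonlocal serial
        for name, element, (dx, dy, dz) in _RESIDUE_TEMPLATE:
            serial += 1
            y_off = -dy if flip else dy
            lines.append(
                _pdb_atom_line(serial, name, resname, chain, resseq,
                               origin[0] + dx, origin[1] + y_off, origin[2] + dz,
                               element)
            )

    for i, resname in enumerate(residues_a):
        place("A", resname, i + 1, (i * spacing, 0.0, 0.0), flip=False)
    for i, resname in enumerate(residues_b):
        dy = (spec.complex_contact_separation if i in contact_idx
              else spec.complex_far_separation)
        # chain B residues point back toward chain A so the closest approach
        # is the declared separation between the facing atoms
        place("B", resname, i + 1, (i * spacing, dy, 0.0), flip=True)
    lines.append("END")

    if class_map is None:
        from .affinity import load_residue_classes

        class_map = load_residue_classes()
    ic_counts = {
        "charged_charged": 0, "charged_apolar": 0, "charged_polar": 0,
        "polar_polar": 0, "polar_apolar": 0, "apolar_apolar": 0,
    }
    contact_pairs = []
    for i in contact_idx:
        cls = frozenset([class_map[residues_a[i]], class_map[residues_b[i]]])
        if cls == frozenset(["charged"]):
            key = "charged_charged"
        elif cls == frozenset(["polar"]):
            key = "polar_polar"
        elif cls == frozenset(["apolar"]):
            key = "apolar_apolar"
        elif cls == frozenset(["charged", "apolar"]):
            key = "charged_apolar"
        elif cls == frozenset(["charged", "polar"]):
            key = "charged_polar"
        else:
            key = "polar_apolar"
        ic_counts[key] += 1
        contact_pairs.append((("A", str(i + 1)), ("B", str(i + 1))))

    truth = ToyComplexTruth(
        n_atoms=serial, contact_pairs=contact_pairs, ic_counts=ic_counts,
        residues_a=residues_a, residues_b=residues_b,
    )
    return "\n".join(lines) + "\n", truth


@dataclass(frozen=True)
class PeptideFixture:
    """One screened candidate peptide with its published prediction scores.

    ``None`` marks a score printed below the 0.5 reporting threshold.
    """

    sequence: str
    ace_inhibitory: float | None
    antihypertensive: float | None
    antidiabetic: float | None
    dppiv_inhibitory: float | None


#: The twelve candidate peptides from milkfish muscle hydrolysates with
#: their published per-activity screening scores (annotations, not computed).
CANDIDATE_PEPTIDES: tuple[PeptideFixture, ...] = (
    PeptideFixture("PMNPPK", 0.977, None, None, None),
    PeptideFixture("VNPYKWL", 0.663, None, None, None),
    PeptideFixture("AAPNF", 0.51, None, None, None),
    PeptideFixture("PPPPV", 0.582, None, None, None),
    PeptideFixture("PMIPG", None, 0.818, None, None),
    PeptideFixture("YPPPT", None, 0.837, None, None),
    PeptideFixture("AMYF", 0.528, 0.903, None, None),
    PeptideFixture("PPPS", 0.591, 0.957, None, None),
    PeptideFixture("MVWH", 0.612, 0.936, None, None),
    PeptideFixture("AAWMIY", None, 0.778, 0.574, None),
    PeptideFixture("AWMIYT", None, 0.517, 0.519, None),
    PeptideFixture("MQML", None, None, 0.813, 0.594),
)


def candidate_peptides() -> list[PeptideFixture]:
    """The twelve screened candidate peptides with their score annotations."""
    return list(CANDIDATE_PEPTIDES)
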