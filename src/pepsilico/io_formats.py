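"""Readers and writers for the standard formats the pipeline touches.

FASTA protein records, BIOPEP-style bioactivity motif tables (TSV) and
two-group protein-peptide complex structures (PDB coordinate files) are
validated strictly on the way in: only the 20 canonical one-letter residue
codes are accepted in sequences, because every downstream quantity (masses,
hydropathy, cleavage rules) is defined over that alphabet and a permissive
parser would silently corrupt them.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

logger = logging.getLogger(__name__)

#: The 20 canonical one-letter amino-acid codes.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Three-letter -> one-letter residue code map (canonical residues only).
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: Residue names treated as solvent when parsing PDB files.
WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein (or peptide) sequence: the unit of digestion and profiling."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        validate_sequence(self.sequence, record_id=self.id)
        if not self.id:
            raise FormatError("protein record id must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BioactivityEntry:
    """A database fragment with a controlled activity label (BIOPEP-style)."""

    fragment: str
    activity: str
    source_id: str = ""

    def __post_init__(self) -> None:
        if len(self.fragment) < 1:
            raise FormatError("bioactivity fragment must be non-empty")
        if not self.activity:
            raise FormatError("activity label must be non-empty")
        validate_sequence(self.fragment, record_id=self.source_id or self.fragment)


@dataclass(frozen=True)
class Atom:
    """A heavy atom of a parsed complex (coordinates in Angstrom)."""

    chain: str
    resnum: str  # 1-based residue number as given, insertion code appended
    resname: str
    name: str
    x: float
    y: float
    z: float
    element: str


@dataclass
class ComplexStructure:
    """Heavy atoms of a two-group complex (e.g. enzyme chains vs peptide)."""

    atoms: list[Atom]
    group_a: frozenset[str]
    group_b: frozenset[str]
    unmappable_residues: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise FormatError("both chain groups must be non-empty")
        if self.group_a & self.group_b:
            raise FormatError("chain groups must be disjoint")
        for atom in self.atoms:
            if not all(math.isfinite(v) for v in (atom.x, atom.y, atom.z)):
                raise FormatError(
                    f"non-finite coordinate in atom {atom.chain}/{atom.resnum}/{atom.name}"
                )

    def atoms_in_group(self, group: Iterable[str]) -> list[Atom]:
        group = set(group)
        return [a for a in self.atoms if a.chain in group]

    def residues(self) -> dict[tuple[str, str], list[Atom]]:
        """Atoms grouped by (chain, residue number) in file order."""
        out: dict[tuple[str, str], list[Atom]] = {}
        for atom in self.atoms:
            out.setdefault((atom.chain, atom.resnum), []).append(atom)
        return out


def validate_sequence(sequence: str, record_id: str = "?") -> None:
    """Reject empty sequences and any character outside the 20-letter alphabet.

    Ambiguity codes (B/J/O/U/X/Z) are rejected too: the mass, hydropathy and
    cleavage tables downstream are undefined for them.
    """
    if not sequence:
        raise FormatError(f"record '{record_id}': empty sequence")
    for pos, ch in enumerate(sequence, start=1):
        if ch not in CANONICAL_AA:
            raise FormatError(
                f"record '{record_id}': illegal residue character {ch!r} "
                f"at position {pos}"
            )


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into validated protein records.

    Sequences are uppercased; duplicate ids and non-canonical residues raise
    :class:`FormatError` naming the offending record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate record id '{rec.id}' in {path}")
        seen.add(rec.id)
        description = rec.description
        if description.startswith(rec.id):
            description = description[len(rec.id):].strip()
        records.append(
            ProteinRecord(id=rec.id, sequence=str(rec.seq).upper(), description=description)
        )
    if not records:
        raise FormatError(f"no records in FASTA file {path}")
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records in wrapped FASTA; read_fasta(write_fasta(x)) == x."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_bioactivity_table(path: str | Path) -> list[BioactivityEntry]:
    """Read a TSV motif table with columns fragment, activity, source_id.

    Duplicate (fragment, activity) pairs are collapsed with a logged warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"fragment", "activity"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    if "source_id" not in df.columns:
        df["source_id"] = ""
    entries: list[BioactivityEntry] = []
    seen: set[tuple[str, str]] = set()
    n_dupes = 0
    for row in df.itertuples(index=False):
        key = (row.fragment, row.activity)
        if key in seen:
            n_dupes += 1
            continue
        seen.add(key)
        entries.append(
            BioactivityEntry(fragment=row.fragment, activity=row.activity,
                             source_id=row.source_id)
        )
    if n_dupes:
        logger.warning("%s: collapsed %d duplicate (fragment, activity) rows", path, n_dupes)
    return entries


def write_bioactivity_table(entries: Sequence[BioactivityEntry], path: str | Path) -> None:
    df = pd.DataFrame(
        [(e.fragment, e.activity, e.source_id) for e in entries],
        columns=["fragment", "activity", "source_id"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_pdb_complex(
    path: str | Path,
    group_a: Iterable[str],
    group_b: Iterable[str],
) -> ComplexStructure:
    """Parse a PDB coordinate file into a two-group heavy-atom structure.

    Dialect: ATOM records of MODEL 1 only; hydrogens, HETATM records, waters
    and alternate locations other than the first are discarded; insertion
    codes are appended to the (string-keyed) residue number. Residues whose
    name is not one of the 20 canonical names are kept but flagged in
    ``unmappable_residues`` rather than silently dropped.
    """
    path = Path(path)
    group_a = frozenset(group_a)
    group_b = frozenset(group_b)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure("complex", str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:  # pragma: no cover - empty file
        raise FormatError(f"{path}: no coordinate model found") from None

    present_chains = {chain.id for chain in model}
    for requested in group_a | group_b:
        if requested not in present_chains:
            raise FormatError(f"{path}: requested chain '{requested}' absent from file")

    wanted = group_a | group_b
    atoms: list[Atom] = []
    unmappable: list[tuple[str, str, str]] = []
    flagged: set[tuple[str, str]] = set()
    for chain in model:
        if chain.id not in wanted:
            continue
        for residue in chain:
            hetflag, resseq, icode = residue.id
            if hetflag != " ":  # HETATM, incl. waters
                continue
            resnum = f"{resseq}{icode.strip()}"
            resname = residue.get_resname().strip()
            if resname not in THREE_TO_ONE and (chain.id, resnum) not in flagged:
                unmappable.append((chain.id, resnum, resname))
                flagged.add((chain.id, resnum))
            for atom in residue:
                element = (atom.element or "").strip().upper()
                if element == "H" or atom.get_name().startswith("H"):
                    continue
                # Biopython keeps only the first (or blank) altloc when
                # building with default settings; enforce explicitly.
                if atom.is_disordered():
                    atom = atom.disordered_get_list()[0]
                x, y, z = atom.coord
                atoms.append(
                    Atom(chain=chain.id, resnum=resnum, resname=resname,
                         name=atom.get_name(), x=float(x), y=float(y), z=float(z),
                         element=element or atom.get_name()[0])
                )

    complex_ = ComplexStructure(atoms=atoms, group_a=group_a, group_b=group_b,
                                unmappable_residues=unmappable)
    for label, group in (("A", group_a), ("B", group_b)):
        if not complex_.atoms_in_group(group):
            raise FormatError(f"{path}: zero atoms in group {label} ({sorted(group)})")
    return complex_


def write_tsv(df: pd.DataFrame, path: str | Path, float_decimals: int = 4) -> None:
    """Write an output table as TSV with a header row and fixed float format."""
    df.to_csv(path, sep="\t", index=False, float_format=f"%.{float_decimals}f")
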