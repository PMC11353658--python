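"""Virtual proteolysis with named protease specificities.

A protease is modelled by a set of cleavage-site patterns, each a
(P1, optional P1') pair: the peptide bond C-terminal to a residue in P1 is
hydrolyzed when the following residue is in P1' (unconditionally if P1' is
unset). Digestion is exhaustive - every matching bond is cut, as in
BIOPEP-UWM's "enzyme action" - with no missed-cleavage model.

The degree of hydrolysis is DH = d / D x 100 %, where d is the number of
hydrolyzed peptide bonds and D the total number of peptide bonds in the
chain (sequence length - 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .io_formats import CANONICAL_AA, ProteinRecord, validate_sequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CleavageSite:
    """One specificity pattern: P1 residue set, optional P1' residue set."""

    p1: frozenset[str]
    p1_prime: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if not self.p1:
            raise ValueError("P1 residue set must be non-empty")
        for s in (self.p1, self.p1_prime or frozenset()):
            bad = set(s) - set(CANONICAL_AA)
            if bad:
                raise ValueError(f"non-canonical residues in site pattern: {sorted(bad)}")

    def matches(self, p1_residue: str, p1_prime_residue: str) -> bool:
        if p1_residue not in self.p1:
            return False
        return self.p1_prime is None or p1_prime_residue in self.p1_prime


@dataclass(frozen=True)
class ProteaseRule:
    """A named protease specificity driving virtual digestion."""

    name: str
    sites: tuple[CleavageSite, ...]
    ec_number: str = ""

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError(f"protease rule '{self.name}' has no cleavage sites")


@dataclass
class DigestResult:
    """Released fragments plus hydrolysis bookkeeping for one digestion.

    Fragment coordinates are 1-based inclusive; the unfiltered fragments
    always concatenate back to the input sequence.
    """

    protein_id: str
    rule_name: str
    fragments: list[tuple[str, int, int]]
    d: int
    D: int
    dh_percent: float
    retained: list[tuple[str, int, int]] = field(default_factory=list)

    @property
    def retained_sequences(self) -> list[str]:
        return [seq for seq, _, _ in self.retained]


def cleavage_sites(sequence: str, rule: ProteaseRule) -> list[int]:
    """Bond indices hydrolyzed by ``rule`` (bond i sits between residues i and i+1, 1-based).

    The terminal position (bond index len(sequence)) is never a bond.
    """
    validate_sequence(sequence)
    cut: list[int] = []
    for i in range(1, len(sequence)):  # bond between residue i and i+1
        p1 = sequence[i - 1]
        p1_prime = sequence[i]
        if any(site.matches(p1, p1_prime) for site in rule.sites):
            cut.append(i)
    return cut


def digest(protein: ProteinRecord, rule: ProteaseRule, min_length: int = 3) -> DigestResult:
    """Hydrolyze one protein exhaustively and apply the fragment-length filter.

    ``min_length`` defaults to 3: single residues and dipeptides are excluded
    from the retained set, the convention used when counting released
    peptides. A single-residue chain has D = 0; its DH is defined as 0.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    seq = protein.sequence
    cuts = cleavage_sites(seq, rule)
    bounds = [0, *cuts, len(seq)]
    fragments = [
        (seq[a:b], a + 1, b) for a, b in zip(bounds[:-1], bounds[1:])
    ]
    d = len(fragments) - 1
    D = len(seq) - 1
    if D == 0:
        logger.info("protein '%s' has a single residue; DH defined as 0", protein.id)
        dh = 0.0
    else:
        dh = d / D * 100.0
    retained = [f for f in fragments if len(f[0]) >= min_length]
    return DigestResult(
        protein_id=protein.id, rule_name=rule.name, fragments=fragments,
        d=d, D=D, dh_percent=dh, retained=retained,
    )


def digest_all(
    proteins: Sequence[ProteinRecord],
    rules: Sequence[ProteaseRule],
    min_length: int = 3,
) -> list[DigestResult]:
    """Digest every protein with every rule independently (one result per pair)."""
    if not proteins or not rules:
        raise ValueError("proteins and rules must be non-empty")
    return [digest(p, r, min_length=min_length) for p in proteins for r in rules]


def digest_table(results: Iterable[DigestResult]) -> pd.DataFrame:
    """Summary table: one row per (protein, rule) with d, D, DH and counts."""
    rows = [
        {
            "protein_id": r.protein_id,
            "enzyme": r.rule_name,
            "d": r.d,
            "D": r.D,
            "dh_percent": r.dh_percent,
            "n_fragments": len(r.fragments),
            "n_retained": len(r.retained),
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def _parse_residue_set(text: str) -> frozenset[str] | None:
    text = text.strip()
    if not text:
        return None
    return frozenset(text)


def load_rule_table(path: str | Path) -> dict[str, ProteaseRule]:
    """Load protease rules from a TSV with columns name, ec_number, p1_residues, p1prime_residues.

    One row per site pattern; rows sharing a name form one rule. An empty
    p1prime_residues field means the site is unconditional.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"name", "p1_residues"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    sites: dict[str, list[CleavageSite]] = {}
    ec: dict[str, str] = {}
    for row in df.itertuples(index=False):
        p1 = _parse_residue_set(row.p1_residues)
        if p1 is None:
            raise ValueError(f"{path}: empty p1_residues for rule '{row.name}'")
        p1p = _parse_residue_set(getattr(row, "p1prime_residues", ""))
        sites.setdefault(row.name, []).append(CleavageSite(p1=p1, p1_prime=p1p))
        ec.setdefault(row.name, getattr(row, "ec_number", ""))
    return {
        name: ProteaseRule(name=name, sites=tuple(patterns), ec_number=ec[name])
        for name, patterns in sites.items()
    }


def default_rules() -> dict[str, ProteaseRule]:
    """The shipped BIOPEP-UWM-style specificities for ficin, papain and stem bromelain.

    The exact specificity definitions used by the web tool are not published
    alongside its outputs; these defaults are an editable convenience (see
    data/protease_rules.tsv), not a ground truth, and rule-sensitive analyses
    should supply their own table.
    """
    with resources.as_file(
        resources.files("pepsilico.data").joinpath("protease_rules.tsv")
    ) as path:
        return load_rule_table(path)
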