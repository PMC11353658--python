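"""Release-frequency statistics for bioactive fragments (BIOPEP-style AE and W).

For a protein of N residues digested by a protease:

* ``AE = d / N`` - the frequency of release of fragments with a given
  activity, where d counts the retained released fragments whose full
  sequence exactly equals a database fragment annotated with that activity
  (multiplicities preserved: the same sequence released at two loci counts
  twice).
* ``A = a / N`` - the occurrence density of database fragments with that
  activity in the intact protein, counting overlapping substring occurrences
  at every start position.
* ``W = AE / A`` - the relative release frequency; undefined (reported as
  None, never infinity) when A = 0.

Exact full-sequence equality is used for AE (released fragments are counted,
not partial containment); substring containment is used only for A.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .digestion import DigestResult, ProteaseRule, digest
from .io_formats import BioactivityEntry, ProteinRecord


@dataclass(frozen=True)
class ActivityProfile:
    """Release-frequency statistics for one (protein, activity) pair."""

    protein_id: str
    activity: str
    d_released: int
    n_residues: int
    ae: float
    a_density: float
    w: float | None  # None when a_density == 0


def _fragments_for(db: Iterable[BioactivityEntry], activity: str) -> set[str]:
    return {e.fragment for e in db if e.activity == activity}


def match_released(
    fragments: Sequence[str | tuple[str, int, int]],
    db: Iterable[BioactivityEntry],
    activity: str,
) -> list[str]:
    """Released fragments whose full sequence matches a db fragment with ``activity``.

    Accepts plain sequences or (sequence, start, end) coordinate tuples.
    An activity absent from the database yields an empty list, not an error.
    """
    targets = _fragments_for(db, activity)
    seqs = [f[0] if isinstance(f, tuple) else f for f in fragments]
    return [s for s in seqs if s in targets]


def release_frequency_AE(d_released: int, n_residues: int) -> float:
    """AE = d / N."""
    if n_residues < 1:
        raise ValueError("protein must have at least one residue")
    if d_released < 0:
        raise ValueError("released-fragment count cannot be negative")
    return d_released / n_residues


def occurrence_count(sequence: str, fragments: Iterable[str]) -> int:
    """Overlapping occurrences of any fragment as a substring of ``sequence``.

    Each (fragment, start position) pair counts once; occurrences of
    different fragments at the same start each count.
    """
    total = 0
    for frag in set(fragments):
        k = len(frag)
        if k == 0 or k > len(sequence):
            continue
        total += sum(
            1 for i in range(len(sequence) - k + 1) if sequence[i:i + k] == frag
        )
    return total


def profile_density_A(
    sequence: str, db: Iterable[BioactivityEntry], activity: str
) -> float:
    """A = overlapping occurrence count of activity fragments / N."""
    targets = _fragments_for(db, activity)
    return occurrence_count(sequence, targets) / len(sequence)


def relative_frequency_W(ae: float, a_density: float) -> float | None:
    """W = AE / A; None when A = 0 (undefined, never infinity)."""
    if a_density < 0:
        raise ValueError("A must be non-negative")
    if a_density == 0:
        return None
    return ae / a_density


def profile_activity(
    protein: ProteinRecord,
    result: DigestResult,
    db: Iterable[BioactivityEntry],
    activity: str,
) -> ActivityProfile:
    """AE, A and W for one protein/digest against one activity label."""
    db = list(db)
    matched = match_released(result.retained, db, activity)
    n = len(protein.sequence)
    ae = release_frequency_AE(len(matched), n)
    a = profile_density_A(protein.sequence, db, activity)
    return ActivityProfile(
        protein_id=protein.id, activity=activity, d_released=len(matched),
        n_residues=n, ae=ae, a_density=a, w=relative_frequency_W(ae, a),
    )


def activity_summary(
    proteins: Sequence[ProteinRecord],
    rules: Sequence[ProteaseRule],
    db: Iterable[BioactivityEntry],
    activities: Sequence[str],
    min_length: int = 3,
) -> pd.DataFrame:
    """Sum of AE over proteins for every (enzyme, activity) pair.

    Layout: one row per enzyme, one column per activity (the overall
    release-potential table of a digestion screen).
    """
    db = list(db)
    rows = []
    for rule in rules:
        row: dict[str, object] = {"enzyme": rule.name}
        for activity in activities:
            total = 0.0
            for protein in proteins:
                result = digest(protein, rule, min_length=min_length)
                total += profile_activity(protein, result, db, activity).ae
            row[activity] = total
        rows.append(row)
    return pd.DataFrame(rows)


def profile_table(
    proteins: Sequence[ProteinRecord],
    rules: Sequence[ProteaseRule],
    db: Iterable[BioactivityEntry],
    activities: Sequence[str],
    min_length: int = 3,
) -> pd.DataFrame:
    """Long-format per-(protein, enzyme, activity) AE/A/W table."""
    db = list(db)
    rows = []
    for protein in proteins:
        for rule in rules:
            result = digest(protein, rule, min_length=min_length)
            for activity in activities:
                p = profile_activity(protein, result, db, activity)
                rows.append(
                    {
                        "protein_id": p.protein_id,
                        "enzyme": rule.name,
                        "activity": p.activity,
                        "d_released": p.d_released,
                        "n_residues": p.n_residues,
                        "AE": p.ae,
                        "A": p.a_density,
                        "W": p.w if p.w is not None else float("nan"),
                    }
                )
    return pd.DataFrame(rows)
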