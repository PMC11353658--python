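"""Contact-based binding-affinity scoring for protein-peptide complexes.

Implements the published contact-based linear model for binding free energy:
interfacial contacts (ICs) are unordered cross-interface residue pairs with
any heavy-atom distance within a cutoff (default 5.5 Angstrom), binned by
the polarity classes of the two residues (charged / polar / apolar); the
non-interacting surface (NIS) is the set of solvent-exposed residues
(relative accessibility >= 5% by default) outside every contact, summarized
as class percentages. The predicted free energy is

    dG = -0.09459 IC_cc - 0.10007 IC_ca + 0.19577 IC_pp - 0.22671 IC_pa
         + 0.18681 %NIS_apolar + 0.3810 %NIS_charged - 15.9433   [kcal/mol]

(the charged-polar and apolar-apolar contact classes carry zero weight, as
published). The dissociation constant follows from dG = RT ln Kd with
R = 1.9872e-3 kcal K^-1 mol^-1 and T = 298.15 K by default.

The module also evaluates the docking stage scores used by flexible
protein-peptide docking (weighted sums of van der Waals, electrostatic,
desolvation, restraint-energy and buried-surface-area terms); the energy
terms themselves are inputs, never computed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io_formats import ComplexStructure
from .surface import residue_rsa

#: Ideal gas constant in kcal K^-1 mol^-1.
GAS_CONSTANT_KCAL = 1.9872e-3
DEFAULT_TEMPERATURE = 298.15

# Printed model coefficients.
_COEF_IC_CHARGED_CHARGED = -0.09459
_COEF_IC_CHARGED_APOLAR = -0.10007
_COEF_IC_POLAR_POLAR = 0.19577
_COEF_IC_POLAR_APOLAR = -0.22671
_COEF_NIS_APOLAR = 0.18681
_COEF_NIS_CHARGED = 0.3810
_INTERCEPT = -15.9433

#: Docking stage weights: (e_vdw, e_elec, e_desolv, bsa, e_air).
HADDOCK_STAGE_WEIGHTS = {
    "it0": (0.01, 0.1, 1.0, -0.01, 0.01),
    "it1": (1.0, 1.0, 1.0, -0.01, 0.1),
    "itw": (1.0, 1.0, 1.0, 0.0, 0.01),
}

_CLASS_PAIR_KEYS = {
    frozenset(["charged"]): "charged_charged",
    frozenset(["charged", "apolar"]): "charged_apolar",
    frozenset(["charged", "polar"]): "charged_polar",
    frozenset(["polar"]): "polar_polar",
    frozenset(["polar", "apolar"]): "polar_apolar",
    frozenset(["apolar"]): "apolar_apolar",
}


class ResidueClassError(ValueError):
    """Raised when a residue cannot be mapped to a polarity class."""


def load_residue_classes(path: str | Path | None = None) -> dict[str, str]:
    """Residue polarity class map (3-letter name -> charged/polar/apolar).

    Ships an editable TSV following the published classification of the
    contact-based affinity model (charged: D/E/H/K/R; polar: N/Q/S/T/W/Y;
    apolar: A/C/F/G/I/L/M/P/V).
    """
    if path is None:
        with resources.as_file(
            resources.files("pepsilico.data").joinpath("residue_classes.tsv")
        ) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return dict(zip(df["resname"], df["polarity_class"]))


@dataclass
class InterfaceStats:
    """Classified interfacial contacts and non-interacting-surface percentages."""

    ic_charged_charged: int = 0
    ic_charged_apolar: int = 0
    ic_charged_polar: int = 0
    ic_polar_polar: int = 0
    ic_polar_apolar: int = 0
    ic_apolar_apolar: int = 0
    nis_apolar_percent: float = 0.0
    nis_charged_percent: float = 0.0
    nis_polar_percent: float = 0.0
    cutoff: float = 5.5
    rsa_threshold: float = 0.05
    contact_pairs: list[tuple[tuple[str, str], tuple[str, str]]] = field(
        default_factory=list
    )

    @property
    def total_contacts(self) -> int:
        return (self.ic_charged_charged + self.ic_charged_apolar
                + self.ic_charged_polar + self.ic_polar_polar
                + self.ic_polar_apolar + self.ic_apolar_apolar)


@dataclass(frozen=True)
class AffinityResult:
    dg: float  # kcal/mol
    kd: float  # mol/L
    temperature: float = DEFAULT_TEMPERATURE
    gas_constant: float = GAS_CONSTANT_KCAL


@dataclass(frozen=True)
class HaddockComponents:
    e_vdw: float
    e_elec: float
    e_desolv: float
    e_air: float
    bsa: float


def _residue_class(resname: str, class_map: dict[str, str]) -> str:
    try:
        return class_map[resname]
    except KeyError:
        raise ResidueClassError(
            f"residue '{resname}' has no polarity class; extend the class map"
        ) from None


def interfacial_contacts(
    complex_: ComplexStructure,
    cutoff: float = 5.5,
    class_map: dict[str, str] | None = None,
) -> InterfaceStats:
    """Count cross-interface residue pairs with any heavy-atom distance <= cutoff.

    Pairs are unordered and binned by unordered polarity-class pair, so the
    counts are invariant under swapping the two chain groups.
    """
    if class_map is None:
        class_map = load_residue_classes()
    atoms_a = complex_.atoms_in_group(complex_.group_a)
    atoms_b = complex_.atoms_in_group(complex_.group_b)
    if not atoms_a or not atoms_b:
        raise ValueError("both chain groups must contain atoms")

    stats = InterfaceStats(cutoff=cutoff)
    if cutoff <= 0:
        return stats

    coords_a = np.array([[a.x, a.y, a.z] for a in atoms_a])
    coords_b = np.array([[a.x, a.y, a.z] for a in atoms_b])
    tree_b = cKDTree(coords_b)
    pairs: set[tuple[tuple[str, str], tuple[str, str]]] = set()
    for i, atom_a in enumerate(atoms_a):
        for j in tree_b.query_ball_point(coords_a[i], cutoff):
            atom_b = atoms_b[j]
            pairs.add(
                ((atom_a.chain, atom_a.resnum), (atom_b.chain, atom_b.resnum))
            )

    residues = complex_.residues()
    for res_a, res_b in sorted(pairs):
        cls_a = _residue_class(residues[res_a][0].resname, class_map)
        cls_b = _residue_class(residues[res_b][0].resname, class_map)
        key = _CLASS_PAIR_KEYS[frozenset([cls_a, cls_b])]
        setattr(stats, f"ic_{key}", getattr(stats, f"ic_{key}") + 1)
        stats.contact_pairs.append((res_a, res_b))
    return stats


def nis_percentages(
    complex_: ComplexStructure,
    stats: InterfaceStats,
    rsa_threshold: float = 0.05,
    probe: float = 1.4,
    n_points: int = 960,
    class_map: dict[str, str] | None = None,
) -> InterfaceStats:
    """Fill the NIS class percentages of ``stats`` in place (and return it).

    Surface residues are those with relative solvent accessibility (computed
    on the complex) at or above ``rsa_threshold``; the non-interacting
    surface is the surface residues participating in no interfacial contact.
    The three class percentages are taken over the NIS residues and sum to 100.
    """
    if class_map is None:
        class_map = load_residue_classes()
    rsa = residue_rsa(complex_, probe=probe, n_points=n_points)
    surface = {key for key, value in rsa.items() if value >= rsa_threshold}
    if not surface:
        raise ValueError("no surface residues at this accessibility threshold")
    interface = {res for pair in stats.contact_pairs for res in pair}
    nis = surface - interface
    residues = complex_.residues()
    counts = {"charged": 0, "polar": 0, "apolar": 0}
    for key in nis:
        counts[_residue_class(residues[key][0].resname, class_map)] += 1
    total = sum(counts.values())
    if total:
        stats.nis_charged_percent = 100.0 * counts["charged"] / total
        stats.nis_polar_percent = 100.0 * counts["polar"] / total
        stats.nis_apolar_percent = 100.0 * counts["apolar"] / total
    else:
        stats.nis_charged_percent = stats.nis_polar_percent = 0.0
        stats.nis_apolar_percent = 0.0
    stats.rsa_threshold = rsa_threshold
    return stats


def predict_binding_affinity(stats: InterfaceStats) -> float:
    """Predicted binding free energy (kcal/mol) from the printed linear model.

    The charged-polar and apolar-apolar contact counts carry zero weight.
    """
    return (
        _COEF_IC_CHARGED_CHARGED * stats.ic_charged_charged
        + _COEF_IC_CHARGED_APOLAR * stats.ic_charged_apolar
        + _COEF_IC_POLAR_POLAR * stats.ic_polar_polar
        + _COEF_IC_POLAR_APOLAR * stats.ic_polar_apolar
        + _COEF_NIS_APOLAR * stats.nis_apolar_percent
        + _COEF_NIS_CHARGED * stats.nis_charged_percent
        + _INTERCEPT
    )


def kd_from_dg(dg: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Dissociation constant (mol/L) from dG = RT ln Kd."""
    return math.exp(dg / (GAS_CONSTANT_KCAL * temperature))


def dg_from_kd(kd: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Binding free energy (kcal/mol) from the dissociation constant."""
    if kd <= 0:
        raise ValueError("Kd must be positive")
    return GAS_CONSTANT_KCAL * temperature * math.log(kd)


def affinity_from_stats(
    stats: InterfaceStats, temperature: float = DEFAULT_TEMPERATURE
) -> AffinityResult:
    dg = predict_binding_affinity(stats)
    return AffinityResult(dg=dg, kd=kd_from_dg(dg, temperature), temperature=temperature)


def analyse_complex(
    complex_: ComplexStructure,
    cutoff: float = 5.5,
    rsa_threshold: float = 0.05,
    temperature: float = DEFAULT_TEMPERATURE,
    class_map: dict[str, str] | None = None,
) -> tuple[InterfaceStats, AffinityResult]:
    """Contacts + NIS + predicted dG and Kd for one parsed complex."""
    if class_map is None:
        class_map = load_residue_classes()
    stats = interfacial_contacts(complex_, cutoff=cutoff, class_map=class_map)
    nis_percentages(complex_, stats, rsa_threshold=rsa_threshold, class_map=class_map)
    return stats, affinity_from_stats(stats, temperature=temperature)


def haddock_stage_score(components: HaddockComponents, stage: str) -> float:
    """Stage-weighted docking score (weights exactly as published)."""
    try:
        w_vdw, w_elec, w_desolv, w_bsa, w_air = HADDOCK_STAGE_WEIGHTS[stage]
    except KeyError:
        raise ValueError(
            f"unknown stage '{stage}'; expected one of {sorted(HADDOCK_STAGE_WEIGHTS)}"
        ) from None
    return (
        w_vdw * components.e_vdw
        + w_elec * components.e_elec
        + w_desolv * components.e_desolv
        + w_bsa * components.bsa
        + w_air * components.e_air
    )
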