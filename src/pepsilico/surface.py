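"""Deterministic Shrake-Rupley solvent-accessible surface areas.

Each heavy atom is covered with a fixed golden-spiral point set on its
solvent-expanded sphere (van der Waals radius + probe radius); the
accessible fraction is the share of points not buried inside any
neighbouring atom's expanded sphere. The point set is deterministic, so
surface areas - and everything derived from them - are bit-reproducible
across runs and platforms.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .io_formats import Atom, ComplexStructure

#: Element-keyed van der Waals radii (Angstrom); unknown elements fall back to 1.80.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
DEFAULT_RADIUS = 1.80

#: Theoretical maximal accessible surface areas per residue (Angstrom^2),
#: used to normalize residue ASA into relative solvent accessibility.
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


def golden_spiral_points(n: int) -> np.ndarray:
    """``n`` near-uniform unit-sphere points from the golden-angle spiral."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = np.pi * (1.0 + 5.0 ** 0.5) * (i + 0.5)
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def atom_radius(atom: Atom) -> float:
    return VDW_RADII.get(atom.element.upper(), DEFAULT_RADIUS)


def shrake_rupley(
    atoms: list[Atom], probe: float = 1.4, n_points: int = 960
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Angstrom^2)."""
    if not atoms:
        return np.zeros(0)
    coords = np.array([[a.x, a.y, a.z] for a in atoms])
    radii = np.array([atom_radius(a) for a in atoms]) + probe
    sphere = golden_spiral_points(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * radii.max()
    areas = np.zeros(len(atoms))
    for i in range(len(atoms)):
        pts = coords[i] + radii[i] * sphere
        neighbours = [j for j in tree.query_ball_point(coords[i], max_reach) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
        areas[i] = accessible.mean() * 4.0 * np.pi * radii[i] ** 2
    return areas


def residue_rsa(
    complex_: ComplexStructure, probe: float = 1.4, n_points: int = 960
) -> dict[tuple[str, str], float]:
    """Relative solvent accessibility per (chain, residue number) on the complex.

    Residue ASA (summed over its heavy atoms) divided by the theoretical
    maximal ASA for that residue type; residues with names outside the
    reference table get RSA = NaN (they were already flagged at parse time).
    """
    areas = shrake_rupley(complex_.atoms, probe=probe, n_points=n_points)
    asa: dict[tuple[str, str], float] = {}
    names: dict[tuple[str, str], str] = {}
    for atom, area in zip(complex_.atoms, areas):
        key = (atom.chain, atom.resnum)
        asa[key] = asa.get(key, 0.0) + float(area)
        names[key] = atom.resname
    out: dict[tuple[str, str], float] = {}
    for key, area in asa.items():
        ref = MAX_ASA.get(names[key])
        out[key] = area / ref if ref else float("nan")
    return out
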