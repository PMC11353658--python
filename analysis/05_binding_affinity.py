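#!/usr/bin/env python
"""Binding-affinity bookkeeping: Kd from published binding free energies,
and the full contact-based scoring chain on a synthetic complex.

First converts the published per-peptide binding free energies (from docking
followed by contact-based prediction) into dissociation constants at
298.15 K via dG = RT ln Kd. Then demonstrates the structural route end to
end on a generated toy complex whose interfacial contacts are known by
construction: parse, count and classify contacts, compute NIS percentages
from deterministic surface areas, and evaluate the linear affinity model.
"""

from pathlib import Path

import pandas as pd

from pepsilico.affinity import analyse_complex, kd_from_dg
from pepsilico.io_formats import read_pdb_complex, write_tsv
from pepsilico.synthetic_data import SyntheticSpec, generate_toy_complex

BASE = Path(__file__).resolve().parent.parent / "results"

# Published binding free energies (kcal/mol) for the screened peptides
# against their targets; Kd recomputed here from the printed dG.
PUBLISHED_DG = [
    ("VNPYKWL", "ACE", -9.6), ("PMNPPK", "ACE", -9.9), ("PPPPV", "ACE", -12.3),
    ("PMIPG", "ACE", -10.6), ("YPPPT", "ACE", -10.4), ("AAPNF", "ACE", -8.5),
    ("AMYF", "ACE", -10.9), ("MVWH", "ACE", -11.0), ("PPPS", "ACE", -8.8),
    ("AWMIYT", "DPPIV", -9.7), ("AAWMIY", "DPPIV", -9.1), ("MQML", "DPPIV", -8.6),
]

rows = [
    {"peptide": pep, "target": tgt, "dg_kcal_mol": dg,
     "kd_molar": kd_from_dg(dg, 298.15)}
    for pep, tgt, dg in PUBLISHED_DG
]
kd_table = pd.DataFrame(rows)
write_tsv(kd_table, BASE / "kd_from_dg.tsv", float_decimals=4)
print("dissociation constants at 298.15 K from published binding energies:")
for row in rows:
    print(f"  {row['peptide']:>8s} ({row['target']:5s}) "
          f"dG = {row['dg_kcal_mol']:6.1f} kcal/mol -> Kd = {row['kd_molar']:.2e} M")

# structural demonstration on a toy complex with engineered contacts
spec = SyntheticSpec(seed=2024, complex_n_residues=10, complex_n_contacts=4)
pdb_text, truth = generate_toy_complex(spec)
pdb_path = BASE / "toy_complex.pdb"
pdb_path.write_text(pdb_text)
complex_ = read_pdb_complex(pdb_path, ["A"], ["B"])
stats, result = analyse_complex(complex_, cutoff=5.5, rsa_threshold=0.05)

print(f"\ntoy complex: {truth.n_atoms} atoms, "
      f"{len(truth.contact_pairs)} engineered contacts, "
      f"{stats.total_contacts} recounted by the contact model")
print(f"  NIS percentages  apolar {stats.nis_apolar_percent:.1f}  "
      f"charged {stats.nis_charged_percent:.1f}  polar {stats.nis_polar_percent:.1f}")
print(f"  predicted dG = {result.dg:.4f} kcal/mol, Kd = {result.kd:.3e} M")

affinity_df = pd.DataFrame([{
    "n_atoms": truth.n_atoms,
    "contacts_engineered": len(truth.contact_pairs),
    "contacts_counted": stats.total_contacts,
    "nis_apolar_percent": stats.nis_apolar_percent,
    "nis_charged_percent": stats.nis_charged_percent,
    "nis_polar_percent": stats.nis_polar_percent,
    "dg_kcal_mol": result.dg,
    "kd_molar": result.kd,
}])
write_tsv(affinity_df, BASE / "toy_affinity.tsv")
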