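#!/usr/bin/env python
"""Physicochemical profiles of the protein panel.

Computes the ProtParam-style descriptor set per protein - masses, charged
residue counts, pI, GRAVY, aliphatic and instability indices, extinction
coefficients and the five-class amino-acid distribution - and summarizes
the stability split.
"""

from pathlib import Path

from pepsilico.io_formats import read_fasta, write_tsv
from pepsilico.pipeline import physchem_table

BASE = Path(__file__).resolve().parent.parent / "results"
proteins = read_fasta(BASE / "inputs" / "proteins.fasta")

table = physchem_table(proteins)
write_tsv(table, BASE / "physchem.tsv")

print(table[["id", "mw_average", "neg_residues", "pos_residues", "pi",
             "gravy", "aliphatic_index", "instability_index",
             "stability_class"]].round(3).to_string(index=False))
n_stable = (table.stability_class == "stable").sum()
print(f"\n{n_stable}/{len(table)} proteins classified stable "
      "(instability index <= 40)")
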