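#!/usr/bin/env python
"""Generate the study inputs: a synthetic muscle-protein panel, a small
bioactivity motif database, and the screened candidate-peptide score table.

The synthetic panel stands in for the nine muscle-protein sequences of the
original screen (which require a UniProt fetch); its size and lengths are
chosen to be comparable. Everything is seeded, so reruns are byte-identical.
"""

from pathlib import Path

from pepsilico.io_formats import BioactivityEntry, write_bioactivity_table, write_fasta, write_tsv
from pepsilico.pipeline import fixture_score_frame
from pepsilico.synthetic_data import SyntheticSpec, generate_motif_db, generate_proteins

OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"
OUT.mkdir(parents=True, exist_ok=True)

spec = SyntheticSpec(seed=2024, n_proteins=9, protein_length=300)
proteins = generate_proteins(spec)
write_fasta(proteins, OUT / "proteins.fasta")
print(f"wrote {len(proteins)} synthetic proteins "
      f"({proteins[0].id}..{proteins[-1].id}, {len(proteins[0])} residues each)")

# Motif database: half random fragments, half fragments the proteases
# actually release from this panel - emulating a curated database whose
# holdings overlap the substrate proteome (otherwise every AE is zero).
import numpy as np

from pepsilico.digestion import default_rules, digest_all

rng = np.random.default_rng(spec.seed + 10)
released = sorted({
    seq
    for result in digest_all(proteins, list(default_rules().values()), min_length=3)
    for seq in result.retained_sequences
    if len(seq) <= 5
})
activities = ("ACE inhibitor", "DPP IV inhibitor", "antioxidative")
sampled = rng.choice(released, size=12, replace=False)
known = [
    BioactivityEntry(fragment=str(frag), activity=str(rng.choice(activities)),
                     source_id="panel-derived")
    for frag in sampled
]
db = known + generate_motif_db(spec, n_fragments=12)
write_bioactivity_table(db, OUT / "motifs.tsv")
print(f"wrote {len(db)}-fragment motif database "
      f"({len(known)} panel-derived, {len(db) - len(known)} random) "
      f"covering {sorted(set(activities))}")

scores = fixture_score_frame()
write_tsv(scores, OUT / "candidate_scores.tsv")
print(f"wrote score annotations for {len(scores)} screened candidate peptides")
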