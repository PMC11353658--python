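#!/usr/bin/env python
"""Screen the twelve candidate peptides by their prediction scores and
compute their drug-likeness descriptors.

The score annotations (general bioactivity and per-activity predictions from
external ML screens) assign nine peptides to the ACE/antihypertensive group
and three to the DPPIV/antidiabetic group at the 0.5 specific-score
threshold. Descriptors are sequence-derived: monoisotopic mass, N+O
hydrogen-bond acceptors, H-on-N/O donors, additive logP estimate, Ertl TPSA
and the four-criterion rule-of-five violation count.
"""

from pathlib import Path

import pandas as pd

from pepsilico.io_formats import write_tsv
from pepsilico.pipeline import druglikeness_table, screen_by_scores

BASE = Path(__file__).resolve().parent.parent / "results"
scores = pd.read_csv(BASE / "inputs" / "candidate_scores.tsv", sep="\t", dtype=str)

screened = screen_by_scores(scores, general_threshold=0.7, specific_threshold=0.5)
write_tsv(screened, BASE / "screen.tsv")
n_ace = (screened.target_group == "ACE").sum()
n_dppiv = (screened.target_group == "DPPIV").sum()
print(f"{len(screened)} candidates: {n_ace} ACE/antihypertensive, "
      f"{n_dppiv} DPPIV/antidiabetic")

druglike = druglikeness_table(list(screened.sequence), mode="lipinski4")
write_tsv(druglike, BASE / "druglike.tsv")
print("\nsequence-derived descriptors and rule-of-five violations:")
print(druglike[["sequence", "mw_mono", "hba", "hbd", "logp_est", "tpsa_est",
                "ro5_violations"]].round(3).to_string(index=False))

compliant = druglike[druglike.ro5_violations == 0]
print(f"\nfully rule-of-five-compliant: {', '.join(compliant.sequence)}")
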