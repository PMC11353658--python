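# Methods

`pepsilico` implements an in-silico bioactive-peptide discovery workflow for
muscle-protein substrates: virtual proteolysis, release-frequency
statistics, physicochemical and drug-likeness profiling, and contact-based
binding-affinity scoring. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic test data does and
does not establish.

## Virtual proteolysis

A protease is a named set of cleavage-site patterns, each a
(P1, optional P1') pair over the 20-letter alphabet: the bond C-terminal to
a P1 residue is hydrolyzed when the next residue is in P1' (unconditionally
when P1' is unset). Digestion is exhaustive - every matching bond is cut,
with no missed-cleavage or kinetic model - which is the convention of
database-driven "enzyme action" tools. Fragments carry 1-based inclusive
coordinates and always partition the input.

The degree of hydrolysis is `DH = d/D x 100 %` with `d` the number of cut
bonds and `D = L - 1` the total bonds of an `L`-residue chain. A
single-residue chain has `D = 0`; its DH is defined as 0 (logged) to avoid
0/0. The retained-fragment filter defaults to `min_length = 3`, excluding
single residues and dipeptides from released-peptide counts; it is
configurable.

Shipped specificities for ficin (EC 3.4.22.3), papain (EC 3.4.22.2) and
stem bromelain (EC 3.4.22.32) live in an editable TSV
(`data/protease_rules.tsv`): ficin cleaves after aromatic residues (F/Y/W),
papain after K/R unless valine follows, bromelain after K/A/Y/G. These are
plausible plant-cysteine-protease specificities in the style of the
BIOPEP-UWM enzyme tables, shipped as a convenience; the exact specificity
definitions behind any particular web-tool output are versioned and not
published with it, so every rule-sensitive test in this package uses
synthetic rules, and absolute fragment counts obtained with the defaults
should not be compared against web-tool outputs.

## Release-frequency statistics

For a protein of `N` residues and an activity label:

* `AE = d/N`, where `d` counts retained released fragments whose full
  sequence exactly equals a database fragment carrying that activity
  (multiplicity preserved: one sequence released at two loci counts twice).
  Exact equality is used because the statistic counts released peptides,
  not partial containment.
* `A = a/N`, where `a` counts occurrences of any database fragment with
  that activity as a substring of the intact protein, at every start
  position, overlaps allowed. This is the standard "frequency of occurrence
  of bioactive fragments" and was adopted as the denominator of `W` because
  the ratio `W = AE/A` is otherwise left without a defined denominator in
  the workflow this package reimplements.
* `W = AE/A`, reported as undefined (None/NaN, never infinity) when
  `A = 0`.

Under these conventions every exact released match is also a substring
occurrence, so `d <= a` and `AE <= A`; the test suite asserts this on
randomized digests. Summary tables report `sum(AE)` over proteins per
(enzyme, activity). Absolute values of such sums depend entirely on the
motif database's holdings, so they are exercised on synthetic databases and
never compared to published database-dependent tables.

## Physicochemical descriptors

All descriptors are classic sequence-only statistics:

* **Masses.** Residue masses + one water. Monoisotopic residue masses are
  derived from a single elemental-composition table
  (`chemistry.py`), so the residue-sum route and the molecular-formula
  route agree to machine precision; average masses use the standard
  average-isotope residue table. Protein-scale reporting uses average
  masses; peptide drug-likeness uses monoisotopic (the convention of the
  descriptor tables this package reproduces).
* **GRAVY**: mean Kyte-Doolittle hydropathy (bounded by the scale extremes
  [-4.5, 4.5]).
* **Aliphatic index** (Ikai): `X(Ala) + 2.9 X(Val) + 3.9 (X(Ile)+X(Leu))`
  in mole-percent.
* **Instability index** (Guruprasad): `(10/L) x` sum of published dipeptide
  weights (imported from Biopython's copy of the published DIWV table);
  "unstable" iff strictly greater than 40.
* **Isoelectric point**: bisection on [0, 14] of the Henderson-Hasselbalch
  net charge (termini plus D/E/C/Y and H/K/R side chains) to
  |charge| < 1e-4. The titration function is strictly decreasing, so the
  root is unique and the bracket choice is immaterial. Two named pKa sets
  ship: `bjellqvist` (default; residue-specific N-terminal pKa, the set
  used by the classic web tool) and `emboss`. Computed pI values should
  only ever be compared across tools at ~0.1 pH tolerance because pKa sets
  differ.
* **Extinction coefficient** (Gill-von Hippel): `5500 nW + 1490 nY`, plus
  `125 floor(nC/2)` when cystines are counted oxidized.
* **Half-life**: static N-end-rule lookup by N-terminal residue
  (mammalian/yeast/E. coli columns); indexing only, no computation.
* **Five-class composition**: negative (D, E), positive (K, R), non-polar
  (V, P, M, L, I, G, A), polar (T, S, Q, N, H, C), aromatic (Y, W, F) -
  a complete partition of the alphabet, so fractions sum to 1.

Only the 20 canonical residues are accepted anywhere; ambiguity codes
(B/J/O/U/X/Z) are rejected at parse time with the record and position named,
because every table above is undefined for them.

## Drug-likeness descriptors

Residue templates encode peptide-bonded element counts; the chain adds one
water. From these:

* **HBA** = total N + O atoms (the Lipinski acceptor convention).
* **HBD** = hydrogens on N or O: N-terminal amine (2 H; proline 1),
  backbone amide H per non-proline non-terminal residue (proline none),
  side-chain N-H/O-H (thiol S-H excluded), C-terminal carboxyl (1).
* **TPSA**: Ertl fragment additivity resolved by terminus context -
  backbone amide N-H 12.03, proline backbone N 3.24, N-terminal NH2 26.02
  (proline 12.03), backbone carbonyl O 17.07, C-terminal COOH 37.30, plus
  side-chain fragment sums; sulfur contributes nothing, as in the original
  parameterization. This reproduces graph-based Ertl TPSA exactly (the
  test suite cross-checks against RDKit on random sequences).
* **logP**: a transparent additive estimate - Fauchere-Pliska side-chain
  hydrophobicity plus fixed increments per backbone unit (-0.90) and for
  the zwitterionic termini (-1.00). It deliberately does not reproduce
  machine-learned partition coefficients; its role is rule-of-five
  bookkeeping, where every unmodified oligopeptide sits far below the
  logP = 5 limit, so compliance decisions are insensitive to the estimator.

**Rule of five**: `lipinski4` (default) counts violations of MW <= 500 Da,
HBA <= 10, HBD <= 5, logP <= 5; `extended5` adds TPSA <= 140 A^2. All
limits are inclusive. Both modes exist because published peptide
drug-likeness tables mix the two conventions row by row; counts that depend
on the mode or on the logP method are not asserted anywhere.

## Contact-based affinity scoring

* **Interfacial contacts**: unordered cross-group residue pairs with any
  heavy-atom distance <= cutoff (default 5.5 A), classified by an editable
  polarity map (charged: D/E/H/K/R; polar: N/Q/S/T/W/Y; apolar:
  A/C/F/G/I/L/M/P/V) following the published contact-based predictor.
  Counting is KD-tree-accelerated and validated against a quadratic
  all-pairs oracle; counts are symmetric under swapping the groups.
* **Surface**: Shrake-Rupley with a fixed 960-point golden-spiral sphere,
  probe 1.4 A, element vdW radii (C 1.70, N 1.55, O 1.52, S 1.80). The
  deterministic point set makes surface areas bit-reproducible. Residue
  relative accessibility uses published theoretical maximal ASA values.
* **NIS**: surface residues (RSA >= 5% by default) in no contact;
  percentages are taken per class over the NIS residues, so the three
  percentages sum to 100.
* **Affinity model**: the printed linear equation
  `dG = -0.09459 IC_cc - 0.10007 IC_ca + 0.19577 IC_pp - 0.22671 IC_pa
  + 0.18681 %NIS_apolar + 0.3810 %NIS_charged - 15.9433` kcal/mol; the
  charged-polar and apolar-apolar counts are carried with zero weight,
  exactly as printed.
* **Kd**: `Kd = exp(dG/(RT))` with `R = 1.9872e-3 kcal K^-1 mol^-1`,
  default `T = 298.15 K`; the round trip is exact to machine precision.
  Published Kd values derived from binding energies printed at 0.1 kcal/mol
  resolution are only comparable at ~5-10%, which is the tolerance used.
* **Docking stage scores**: it0/it1/itw weighted sums over externally
  supplied energy terms (EvdW, Eelec, Edesolv, EAIR, BSA). No docking,
  pose generation or energy evaluation happens in this package; the terms
  are inputs.

PDB parsing keeps heavy atoms of ATOM records in model 1 only, drops
HETATM/waters/hydrogens, keeps the first alternate location, appends
insertion codes to string residue keys, and flags (rather than drops)
residues with non-canonical names.

## Synthetic data

The generators produce: seeded random proteins with a controlled
composition (defaults: 9 proteins of 300 residues, uniform composition -
sized like a small muscle-protein panel); small motif databases; and toy
two-chain complexes on a 20-A grid where selected opposite residue pairs
are brought to 6.0 A (inside the 5.5-A heavy-atom cutoff via facing atoms,
outside clash range) and all others held at 18 A, so the generator can
declare its interfacial contacts by construction. Toy residues carry
backbone N/CA/C/O plus one side-chain carbon.

What passing on synthetic data shows: the counting, partition, statistic
and scoring machinery is correct against independent oracles. What it does
not show: anything about real proteome composition, real protease
preference, real database holdings, or real interface geometry (toy
complexes have no packing, no rotamers, no buried interface to speak of).
Published absolute outputs that depend on those (fragment counts per
protein, DH per enzyme, summed-AE tables, docked-pose energies and the
affinity values of specific complexes) are therefore demonstrated, not
reproduced.

The twelve screened candidate peptides ship as fixtures with their
published prediction-score annotations (general bioactivity and
per-activity scores). The scores come from external ML screens and are
never recomputed; the screening step filters at >= 0.7 (general) and flags
at >= 0.5 (specific), with "-" entries counted as below threshold. Because
two candidates carry both antihypertensive and antidiabetic flags, the
screen also assigns one exclusive target group per peptide with
DPPIV/antidiabetic precedence - reproducing the 9 + 3 split of the original
screen - while reporting the raw flags separately.

## Known limitations

* Shipped protease rules are plausible defaults, not validated
  specificities; swap in your own TSV for any rule-sensitive analysis.
* The logP estimate is additive and unsuitable for comparing against ML
  partition coefficients; it exists for rule-of-five bookkeeping.
* NIS percentages are computed over NIS residues (so they sum to 100);
  tools that normalize over all surface residues will differ when the
  interface is large.
* No docking: affinity scoring requires a supplied complex structure, and
  stage scores require supplied energy terms.
* Descriptor comparisons against published values for specific UniProt
  accessions require fetching those sequences (network); the package ships
  no third-party sequence data.
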