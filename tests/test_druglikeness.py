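"""Sequence-derived drug-likeness descriptors and rule-of-five evaluation.

The twelve milkfish candidate peptides have published monoisotopic masses,
N+O acceptor counts, H-on-N/O donor counts and Ertl polar surface areas;
all four columns are reproduced here from residue templates alone. The
published partition coefficients come from a machine-learned model and are
deliberately NOT asserted against the shipped additive estimate.
"""

from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepsilico.druglikeness import (
    SIDECHAIN_DONOR_H,
    hba_count,
    hbd_count,
    logp_estimate,
    molecular_formula,
    formula_string,
    monoisotopic_mass_from_formula,
    peptide_descriptors,
    ro5_violations,
    tpsa_estimate,
)
from pepsilico.io_formats import CANONICAL_AA
from pepsilico.physchem import molecular_weight

SEQUENCES = st.text(alphabet=CANONICAL_AA, min_size=1, max_size=40)

# Published descriptor rows: sequence -> (MW mono, HBA, HBD, TPSA).
REFERENCE_DESCRIPTORS = {
    "VNPYKWL": (918.50, 20, 14, 334.26),
    "PMNPPK": (682.35, 16, 9, 246.36),
    "PPPPV": (505.29, 11, 3, 139.36),
    "AAPNF": (518.25, 13, 8, 214.02),
    "YPPPT": (573.28, 13, 6, 193.81),
    "PMIPG": (513.26, 11, 5, 156.94),
    "AMYF": (530.22, 10, 7, 170.85),
    "PPPS": (396.20, 10, 4, 139.28),
    "MVWH": (571.26, 12, 8, 195.09),
    "AAWMIY": (753.35, 15, 10, 244.84),
    "AWMIYT": (783.36, 16, 11, 265.07),
    "MQML": (521.23, 11, 8, 193.71),
}


class TestMolecularFormula:
    def test_glycine_free_amino_acid(self):
        assert formula_string(molecular_formula("G")) == "C2H5NO2"

    def test_template_algebra_example(self):
        # 3 x Pro(C5H7NO) + Ser(C3H5NO2) + H2O
        assert formula_string(molecular_formula("PPPS")) == "C18H28N4O6"

    @settings(max_examples=100, derandomize=True)
    @given(a=SEQUENCES, b=SEQUENCES)
    def test_concatenation_additivity(self, a, b):
        combined = molecular_formula(a + b)
        expected = molecular_formula(a) + molecular_formula(b)
        expected.subtract({"H": 2, "O": 1})  # one condensation
        assert +combined == +expected  # unary + drops zero-count elements


class TestAcceptorsAndDonors:
    @pytest.mark.parametrize(
        "seq,hba,hbd", [(s, v[1], v[2]) for s, v in REFERENCE_DESCRIPTORS.items()]
    )
    def test_published_counts(self, seq, hba, hbd):
        assert hba_count(seq) == hba
        assert hbd_count(seq) == hbd

    def test_glycine(self):
        assert hba_count("G") == 3  # 1 N + 2 O
        assert hbd_count("G") == 3  # NH2 (2) + COOH (1)

    @settings(max_examples=100, derandomize=True)
    @given(seq=SEQUENCES)
    def test_hba_equals_n_plus_o_of_formula(self, seq):
        counts = molecular_formula(seq)
        assert hba_count(seq) == counts["N"] + counts["O"]

    @pytest.mark.parametrize("aa", CANONICAL_AA)
    def test_hbd_matches_per_residue_table_on_homodipeptides(self, aa):
        """Independent recount: termini contributions plus two side chains."""
        nterm = 1 if aa == "P" else 2
        amide = 0 if aa == "P" else 1
        expected = nterm + amide + 1 + 2 * SIDECHAIN_DONOR_H.get(aa, 0)
        assert hbd_count(aa + aa) == expected


class TestMassConsistency:
    @pytest.mark.parametrize(
        "seq,mw", [(s, v[0]) for s, v in REFERENCE_DESCRIPTORS.items()]
    )
    def test_published_monoisotopic_masses(self, seq, mw):
        assert monoisotopic_mass_from_formula(molecular_formula(seq)) == pytest.approx(
            mw, abs=0.01
        )

    @settings(max_examples=100, derandomize=True)
    @given(seq=SEQUENCES)
    def test_formula_mass_matches_residue_mass_route(self, seq):
        """Two independent computations of the same quantity agree to 1e-4 Da."""
        via_formula = monoisotopic_mass_from_formula(molecular_formula(seq))
        via_residues = molecular_weight(seq, "monoisotopic")
        assert via_formula == pytest.approx(via_residues, abs=1e-4)


class TestTpsa:
    @pytest.mark.parametrize(
        "seq,tpsa", [(s, v[3]) for s, v in REFERENCE_DESCRIPTORS.items()]
    )
    def test_published_polar_surface_areas(self, seq, tpsa):
        assert tpsa_estimate(seq) == pytest.approx(tpsa, abs=0.01)

    def test_polar_exceeds_hydrophobic_at_equal_length(self):
        assert tpsa_estimate("SSSS") > tpsa_estimate("LLLL")

    @settings(max_examples=60, derandomize=True)
    @given(a=SEQUENCES, b=SEQUENCES)
    def test_concatenation_additivity_with_terminal_correction(self, a, b):
        # joining converts a COOH (37.30) + N-terminal amine into a backbone
        # carbonyl (17.07) + amide/tertiary N: the correction is sequence-local
        joined = tpsa_estimate(a + b)
        nterm_b = 12.03 if b[0] == "P" else 26.02
        amide_b = 3.24 if b[0] == "P" else 12.03
        expected = (
            tpsa_estimate(a) + tpsa_estimate(b)
            - 37.30 + 17.07  # a's terminal carboxyl becomes a carbonyl
            - nterm_b + amide_b  # b's amine becomes a backbone nitrogen
        )
        assert joined == pytest.approx(expected, abs=1e-9)


class TestLogP:
    def test_appending_leucine_never_decreases(self, rng):
        from conftest import random_sequence

        for _ in range(20):
            seq = random_sequence(rng, int(rng.integers(1, 30)))
            assert logp_estimate(seq + "L") > logp_estimate(seq)

    def test_aromatic_above_aliphatic(self):
        assert logp_estimate("FFFF") > logp_estimate("AAAA")

    @settings(max_examples=60, derandomize=True)
    @given(seq=SEQUENCES)
    def test_equals_contribution_sum(self, seq):
        from pepsilico.druglikeness import (
            SIDECHAIN_PI,
            _LOGP_BACKBONE_PER_RESIDUE,
            _LOGP_TERMINI,
        )

        expected = (
            sum(SIDECHAIN_PI[aa] for aa in seq)
            + _LOGP_BACKBONE_PER_RESIDUE * len(seq)
            + _LOGP_TERMINI
        )
        assert logp_estimate(seq) == pytest.approx(expected)


class TestAgainstCheminformaticsToolkit:
    """Independent oracle: build the molecule from the sequence with RDKit and
    recompute mass, N+O acceptors, H-on-N/O donors and Ertl TPSA from the
    molecular graph (no residue templates involved)."""

    def test_random_sequences_agree_with_rdkit(self, rng):
        from rdkit import Chem
        from rdkit.Chem import Descriptors, Lipinski, rdMolDescriptors

        from conftest import random_sequence

        for _ in range(30):
            seq = random_sequence(rng, int(rng.integers(1, 12)))
            mol = Chem.MolFromSequence(seq)
            assert mol is not None
            d = peptide_descriptors(seq)
            assert d.mw_monoisotopic == pytest.approx(
                rdMolDescriptors.CalcExactMolWt(mol), abs=1e-3
            )
            assert d.hba == Lipinski.NOCount(mol)
            assert d.hbd == Lipinski.NHOHCount(mol)
            assert d.tpsa_estimate == pytest.approx(Descriptors.TPSA(mol), abs=1e-6)


class TestRuleOfFive:
    def test_compliant_tetrapeptide(self):
        d = peptide_descriptors("PPPS")
        assert d.ro5_violations == 0
        assert all(d.ro5_flags.values())

    def test_two_violations_pentapeptide(self):
        d = peptide_descriptors("PPPPV")
        assert d.ro5_violations == 2
        assert not d.ro5_flags["mw"] and not d.ro5_flags["hba"]
        assert d.ro5_flags["hbd"] and d.ro5_flags["logp"]

    def test_limits_inclusive(self):
        violations, flags = ro5_violations(
            mode="extended5", mw=500.0, hba=10, hbd=5, logp=5.0, tpsa=140.0
        )
        assert violations == 0 and all(flags.values())

    def test_extended_mode_adds_tpsa(self):
        v4, _ = ro5_violations(mode="lipinski4", mw=400, hba=8, hbd=4, logp=1, tpsa=200)
        v5, flags = ro5_violations(mode="extended5", mw=400, hba=8, hbd=4, logp=1, tpsa=200)
        assert (v4, v5) == (0, 1)
        assert not flags["tpsa"]

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            ro5_violations(mode="lipinski6", mw=1, hba=1, hbd=1, logp=1, tpsa=1)

    def test_monotone_in_each_descriptor(self):
        base = dict(mw=400.0, hba=8, hbd=4, logp=2.0, tpsa=100.0)
        v0, _ = ro5_violations(mode="extended5", **base)
        for key, worse in [("mw", 600.0), ("hba", 12), ("hbd", 7),
                           ("logp", 6.5), ("tpsa", 150.0)]:
            v, _ = ro5_violations(mode="extended5", **{**base, key: worse})
            assert v >= v0
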