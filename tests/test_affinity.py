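"""Contact classification, NIS, the linear affinity model and Kd conversion."""

import math

import numpy as np
import pytest

from pepsilico.affinity import (
    HaddockComponents,
    InterfaceStats,
    analyse_complex,
    dg_from_kd,
    haddock_stage_score,
    interfacial_contacts,
    kd_from_dg,
    load_residue_classes,
    nis_percentages,
    predict_binding_affinity,
)
from pepsilico.io_formats import Atom, ComplexStructure, read_pdb_complex
from pepsilico.surface import golden_spiral_points, shrake_rupley
from pepsilico.synthetic_data import SyntheticSpec, generate_toy_complex


def parse_toy(tmp_path, spec: SyntheticSpec):
    pdb_text, truth = generate_toy_complex(spec)
    path = tmp_path / f"toy{spec.seed}.pdb"
    path.write_text(pdb_text)
    return read_pdb_complex(path, ["A"], ["B"]), truth


def brute_force_contacts(complex_: ComplexStructure, cutoff: float) -> set:
    """Independent all-pairs O(n^2) recount of cross-interface residue pairs."""
    atoms_a = complex_.atoms_in_group(complex_.group_a)
    atoms_b = complex_.atoms_in_group(complex_.group_b)
    pairs = set()
    for a in atoms_a:
        for b in atoms_b:
            d = math.dist((a.x, a.y, a.z), (b.x, b.y, b.z))
            if d <= cutoff:
                pairs.add(((a.chain, a.resnum), (b.chain, b.resnum)))
    return pairs


class TestInterfacialContacts:
    def test_distant_chains_have_no_contacts(self, tmp_path):
        spec = SyntheticSpec(seed=11, complex_n_contacts=0)
        complex_, _ = parse_toy(tmp_path, spec)
        stats = interfacial_contacts(complex_)
        assert stats.total_contacts == 0

    def test_zero_cutoff(self, tmp_path):
        complex_, _ = parse_toy(tmp_path, SyntheticSpec(seed=12, complex_n_contacts=4))
        assert interfacial_contacts(complex_, cutoff=0.0).total_contacts == 0

    def test_counts_match_generator_truth_and_brute_force(self, tmp_path):
        for seed in range(8):
            spec = SyntheticSpec(seed=seed, complex_n_residues=10,
                                 complex_n_contacts=seed % 5)
            complex_, truth = parse_toy(tmp_path, spec)
            stats = interfacial_contacts(complex_)
            assert sorted(stats.contact_pairs) == sorted(truth.contact_pairs)
            for key, count in truth.ic_counts.items():
                assert getattr(stats, f"ic_{key}") == count
            assert set(stats.contact_pairs) == brute_force_contacts(complex_, 5.5)

    def test_symmetric_under_group_swap(self, tmp_path):
        pdb_text, _ = generate_toy_complex(SyntheticSpec(seed=13, complex_n_contacts=3))
        path = tmp_path / "swap.pdb"
        path.write_text(pdb_text)
        fwd = interfacial_contacts(read_pdb_complex(path, ["A"], ["B"]))
        rev = interfacial_contacts(read_pdb_complex(path, ["B"], ["A"]))
        for key in ("charged_charged", "charged_apolar", "charged_polar",
                    "polar_polar", "polar_apolar", "apolar_apolar"):
            assert getattr(fwd, f"ic_{key}") == getattr(rev, f"ic_{key}")

    def test_random_geometry_cutoffs_agree_with_oracle(self, rng, tmp_path):
        """Random cutoffs against random toy geometries: KD-tree counting equals
        the quadratic scan."""
        for i in range(10):
            spec = SyntheticSpec(seed=100 + i, complex_n_residues=6,
                                 complex_n_contacts=int(rng.integers(0, 4)))
            complex_, _ = parse_toy(tmp_path, spec)
            cutoff = float(rng.uniform(1.0, 12.0))
            stats = interfacial_contacts(complex_, cutoff=cutoff)
            assert set(stats.contact_pairs) == brute_force_contacts(complex_, cutoff)

    def test_unmappable_residue_class_raises(self, tmp_path):
        complex_, _ = parse_toy(tmp_path, SyntheticSpec(seed=14, complex_n_contacts=2))
        partial_map = {"ALA": "apolar"}  # everything else missing
        with pytest.raises(ValueError, match="polarity class"):
            interfacial_contacts(complex_, class_map=partial_map)


class TestSurface:
    def test_golden_spiral_points_on_unit_sphere(self):
        pts = golden_spiral_points(960)
        assert pts.shape == (960, 3)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)

    def test_isolated_atom_fully_accessible(self):
        atom = Atom("A", "1", "GLY", "CA", 0.0, 0.0, 0.0, "C")
        area = shrake_rupley([atom])[0]
        assert area == pytest.approx(4.0 * math.pi * (1.70 + 1.4) ** 2)

    def test_buried_atom_has_zero_area(self):
        # central atom enclosed by a tight octahedral cage
        center = Atom("A", "1", "GLY", "CA", 0.0, 0.0, 0.0, "C")
        cage = [
            Atom("A", "2", "GLY", "CA", *xyz, "C")
            for xyz in [(2.2, 0, 0), (-2.2, 0, 0), (0, 2.2, 0),
                        (0, -2.2, 0), (0, 0, 2.2), (0, 0, -2.2)]
        ]
        areas = shrake_rupley([center, *cage])
        assert areas[0] == 0.0

    def test_matches_monte_carlo_oracle(self, rng):
        """Independent check: randomly sampled sphere points (different RNG,
        different point placement) give the same accessible fraction to ~2%."""
        atoms = [
            Atom("A", str(i + 1), "GLY", "CA",
                 float(x), float(y), float(z), "C")
            for i, (x, y, z) in enumerate(rng.uniform(-4, 4, size=(6, 3)))
        ]
        ours = shrake_rupley(atoms, n_points=2000)
        radius = 1.70 + 1.4
        coords = np.array([[a.x, a.y, a.z] for a in atoms])
        for i in range(len(atoms)):
            mc = rng.standard_normal((20000, 3))
            mc /= np.linalg.norm(mc, axis=1, keepdims=True)
            pts = coords[i] + radius * mc
            free = np.ones(len(pts), dtype=bool)
            for j in range(len(atoms)):
                if j == i:
                    continue
                free &= np.sum((pts - coords[j]) ** 2, axis=1) > radius ** 2
            expected = free.mean() * 4.0 * np.pi * radius ** 2
            assert ours[i] == pytest.approx(expected, abs=0.02 * 4 * np.pi * radius ** 2)


class TestNis:
    def test_percentages_sum_to_100(self, tmp_path):
        complex_, _ = parse_toy(tmp_path, SyntheticSpec(seed=15, complex_n_contacts=2))
        stats = interfacial_contacts(complex_)
        nis_percentages(complex_, stats)
        total = (stats.nis_apolar_percent + stats.nis_charged_percent
                 + stats.nis_polar_percent)
        assert total == pytest.approx(100.0, abs=1e-6)

    def test_fully_exposed_distant_residues_are_all_nis(self, tmp_path):
        spec = SyntheticSpec(seed=16, complex_n_residues=4, complex_n_contacts=0)
        complex_, truth = parse_toy(tmp_path, spec)
        stats = interfacial_contacts(complex_)
        nis_percentages(complex_, stats)
        class_map = load_residue_classes()
        classes = [class_map[r] for r in truth.residues_a + truth.residues_b]
        expected_charged = 100.0 * classes.count("charged") / len(classes)
        assert stats.nis_charged_percent == pytest.approx(expected_charged)

    def test_impossible_threshold_raises(self, tmp_path):
        complex_, _ = parse_toy(tmp_path, SyntheticSpec(seed=17))
        stats = interfacial_contacts(complex_)
        with pytest.raises(ValueError, match="surface"):
            nis_percentages(complex_, stats, rsa_threshold=10.0)


class TestAffinityModel:
    def test_intercept(self):
        assert predict_binding_affinity(InterfaceStats()) == pytest.approx(-15.9433)

    def test_polar_polar_substitution(self):
        stats = InterfaceStats(ic_polar_polar=10)
        assert predict_binding_affinity(stats) == pytest.approx(-13.9856)

    def test_zero_weight_classes(self):
        # charged-polar and apolar-apolar contacts carry no weight
        assert predict_binding_affinity(
            InterfaceStats(ic_charged_polar=7, ic_apolar_apolar=11)
        ) == pytest.approx(-15.9433)

    def test_dot_product_oracle(self, rng):
        coef = {
            "ic_charged_charged": -0.09459, "ic_charged_apolar": -0.10007,
            "ic_polar_polar": 0.19577, "ic_polar_apolar": -0.22671,
            "nis_apolar_percent": 0.18681, "nis_charged_percent": 0.3810,
        }
        for _ in range(50):
            fields = {k: float(rng.integers(0, 40)) for k in coef}
            stats = InterfaceStats(**{k: (int(v) if k.startswith("ic") else v)
                                      for k, v in fields.items()})
            expected = sum(coef[k] * fields[k] for k in coef) - 15.9433
            assert predict_binding_affinity(stats) == pytest.approx(expected, abs=1e-9)

    def test_linearity_in_components(self, rng):
        intercept = predict_binding_affinity(InterfaceStats())
        s1 = InterfaceStats(ic_polar_polar=3, nis_charged_percent=10.0)
        s2 = InterfaceStats(ic_charged_apolar=5, nis_apolar_percent=20.0)
        s12 = InterfaceStats(ic_polar_polar=3, ic_charged_apolar=5,
                             nis_charged_percent=10.0, nis_apolar_percent=20.0)
        lhs = predict_binding_affinity(s12) - intercept
        rhs = (predict_binding_affinity(s1) - intercept) + (
            predict_binding_affinity(s2) - intercept)
        assert lhs == pytest.approx(rhs, abs=1e-9)


class TestKdConversion:
    def test_zero_energy_unit_kd(self):
        assert kd_from_dg(0.0) == 1.0

    @pytest.mark.parametrize("dg,kd", [(-12.3, 9.30e-10), (-8.5, 5.60e-7)])
    def test_published_conversions_within_10_percent(self, dg, kd):
        assert kd_from_dg(dg) == pytest.approx(kd, rel=0.10)

    def test_round_trip_identity(self, rng):
        for dg in rng.uniform(-20, 5, size=1000):
            assert dg_from_kd(kd_from_dg(dg)) == pytest.approx(dg, rel=1e-12, abs=1e-12)

    def test_nonpositive_kd_rejected(self):
        with pytest.raises(ValueError):
            dg_from_kd(0.0)

    def test_result_invariants(self, tmp_path):
        complex_, _ = parse_toy(tmp_path, SyntheticSpec(seed=18, complex_n_contacts=3))
        _, result = analyse_complex(complex_)
        assert result.kd > 0
        assert result.dg == pytest.approx(
            result.gas_constant * result.temperature * math.log(result.kd), rel=1e-12
        )


class TestHaddockScore:
    def test_zero_components(self):
        zero = HaddockComponents(0, 0, 0, 0, 0)
        for stage in ("it0", "it1", "itw"):
            assert haddock_stage_score(zero, stage) == 0.0

    def test_it0_direct_substitution(self):
        components = HaddockComponents(e_vdw=10, e_elec=10, e_desolv=10, e_air=10, bsa=100)
        assert haddock_stage_score(components, "it0") == pytest.approx(10.2)

    def test_itw_ignores_bsa(self):
        a = HaddockComponents(1, 2, 3, 4, bsa=0)
        b = HaddockComponents(1, 2, 3, 4, bsa=5000)
        assert haddock_stage_score(a, "itw") == haddock_stage_score(b, "itw")

    def test_stage_weights(self):
        components = HaddockComponents(e_vdw=1, e_elec=1, e_desolv=1, e_air=1, bsa=1)
        assert haddock_stage_score(components, "it1") == pytest.approx(
            1 + 1 + 1 - 0.01 + 0.1
        )

    def test_unknown_stage(self):
        with pytest.raises(ValueError, match="unknown stage"):
            haddock_stage_score(HaddockComponents(0, 0, 0, 0, 0), "water")
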