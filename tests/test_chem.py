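"""Exact-mass engine: formulas, residues, modifications, labels, search."""

import math
from itertools import product as cartesian

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from piriminer.chem import (
    MODIFICATIONS,
    MONOISOTOPIC_MASS,
    PROTON_MASS,
    RESIDUE_FORMULAS,
    ElementalFormula,
    IsotopeLabel,
    PeptideProduct,
    apply_modifications,
    formula_search,
    infer_atom_count,
    isotope_shift,
    monoisotopic_mass,
    nominal_mz,
    nominal_shift,
    peptide_formula,
    protonated_mz,
    residue_formula,
)

AA = sorted(RESIDUE_FORMULAS)
cores = st.text(alphabet=AA, min_size=1, max_size=25)
small_formulas = st.builds(
    ElementalFormula,
    st.fixed_dictionaries(
        {},
        optional={e: st.integers(0, 30) for e in ("C", "H", "N", "O", "S")},
    ),
)


class TestElementalFormula:
    def test_parse_and_str_round_trip(self):
        f = ElementalFormula.parse("C5H8O")
        assert f.counts == {"C": 5, "H": 8, "O": 1}
        assert str(f) == "C5H8O"

    def test_arithmetic_is_elementwise(self):
        a = ElementalFormula.parse("C2H3NO")
        b = ElementalFormula.parse("H2O")
        assert (a + b).counts == {"C": 2, "H": 5, "N": 1, "O": 2}
        assert (a + b - b) == a
        assert (2 * b).counts == {"H": 4, "O": 2}

    def test_subtraction_below_zero_rejected(self):
        with pytest.raises(ValueError):
            ElementalFormula.parse("H2O") - ElementalFormula.parse("C")

    def test_isotope_subs_bounded_by_counts(self):
        with pytest.raises(ValueError, match="exceeds"):
            ElementalFormula({"N": 2}, {"15N": 3})

    def test_unsupported_element_rejected(self):
        with pytest.raises(ValueError, match="unsupported"):
            ElementalFormula({"Fe": 1})

    @given(a=small_formulas, b=small_formulas)
    @settings(max_examples=50, deadline=None)
    def test_addition_order_independent(self, a, b):
        assert a + b == b + a
        assert math.isclose(
            monoisotopic_mass(a + b),
            monoisotopic_mass(a) + monoisotopic_mass(b),
            rel_tol=1e-12,
        )


class TestResidues:
    @pytest.mark.parametrize(
        "aa,expected", [("G", "C2H3NO"), ("P", "C5H7NO"), ("C", "C3H5NOS")]
    )
    def test_residue_formula(self, aa, expected):
        assert residue_formula(aa) == ElementalFormula.parse(expected)

    @pytest.mark.parametrize("bad", ["B", "Z", "X", "U", "g"])
    def test_nonstandard_codes_rejected_naming_offender(self, bad):
        with pytest.raises(ValueError, match=repr(bad)):
            residue_formula(bad)

    def test_all_twenty_match_published_residue_masses(self):
        """Independent oracle: pyteomics' residue mass table, <= 1e-4 Da."""
        from pyteomics import mass as pmass

        for aa in AA:
            ours = monoisotopic_mass(residue_formula(aa))
            ref = pmass.std_aa_mass[aa]
            assert abs(ours - ref) <= 1e-4, aa


class TestPeptideFormula:
    def test_cyclic_is_sum_without_water(self):
        assert peptide_formula("GG", "cyclic") == ElementalFormula.parse("C4H6N2O2")

    def test_linear_adds_water(self):
        assert peptide_formula("G", "linear") == ElementalFormula.parse("C2H5NO2")

    def test_empty_and_invalid_rejected(self):
        with pytest.raises(ValueError):
            peptide_formula("", "cyclic")
        with pytest.raises(ValueError):
            peptide_formula("GB", "cyclic")
        with pytest.raises(ValueError):
            peptide_formula("GG", "branched")

    @given(core=cores)
    @settings(max_examples=80, deadline=None)
    def test_linear_minus_cyclic_is_water(self, core):
        diff = monoisotopic_mass(peptide_formula(core, "linear")) - monoisotopic_mass(
            peptide_formula(core, "cyclic")
        )
        assert math.isclose(diff, monoisotopic_mass(ElementalFormula.parse("H2O")),
                            rel_tol=1e-12)

    def test_linear_agrees_with_pyteomics(self):
        """Dual route: our composition sum vs pyteomics peptide masses."""
        from pyteomics import mass as pmass

        for core in ("GTHLYTITP", "TLGCMNGTERCLGLP", "MSGVDYYNP", "WILLADGTRPKNAP"):
            ours = monoisotopic_mass(peptide_formula(core, "linear"))
            assert abs(ours - pmass.calculate_mass(sequence=core)) < 5e-4


class TestMasses:
    def test_water_constant(self):
        assert monoisotopic_mass(ElementalFormula.parse("H2O")) == pytest.approx(
            18.0106, abs=5e-5
        )

    @pytest.mark.parametrize(
        "formula,expected",
        [("C5H8", 68.0626), ("C10H16", 136.1252), ("C2H5NOS", 91.0092),
         ("CH4OS", 63.9983)],
    )
    def test_neutral_fragment_masses(self, formula, expected):
        assert monoisotopic_mass(ElementalFormula.parse(formula)) == pytest.approx(
            expected, abs=5e-5
        )

    def test_cyclic_gthlytitp_protonated(self):
        f = peptide_formula("GTHLYTITP", "cyclic")
        assert protonated_mz(f, 1) == pytest.approx(984.5149, abs=5e-5)

    def test_protonated_water(self):
        assert protonated_mz(ElementalFormula.parse("H2O"), 1) == pytest.approx(
            19.0178, abs=5e-5
        )

    def test_charge_below_one_rejected(self):
        with pytest.raises(ValueError):
            protonated_mz(ElementalFormula.parse("H2O"), 0)

    @given(f=small_formulas, z=st.integers(1, 3))
    @settings(max_examples=60, deadline=None)
    def test_charge_consistency(self, f, z):
        assert math.isclose(
            z * protonated_mz(f, z) - z * PROTON_MASS,
            monoisotopic_mass(f),
            rel_tol=1e-12,
            abs_tol=1e-9,
        )

    def test_nominal_conventions(self):
        # low-res ion readout truncates; mass differences round
        assert nominal_mz(1544.7018) == 1544
        assert nominal_shift(3.9916) == 4
        assert nominal_shift(-68.0626) == -68


class TestModificationAlgebra:
    def test_disulfide_then_cam_reproduces_derivatization_shift(self):
        ss = PeptideProduct("TLGCMNGTERCLGLP", mods={"disulfide": 1})
        cam = PeptideProduct("TLGCMNGTERCLGLP", mods={"cam_cys": 2})
        assert nominal_mz(ss.mz()) == 1544
        assert nominal_mz(cam.mz()) == 1660
        assert nominal_shift(cam.mz() - ss.mz()) == 116

    def test_geranyl_is_exactly_two_prenyl(self):
        add_g, rem_g = MODIFICATIONS["geranyl"]
        add_p, rem_p = MODIFICATIONS["prenyl"]
        assert add_g == 2 * add_p and rem_g == rem_p == ElementalFormula()

    @pytest.mark.parametrize("mod", sorted(MODIFICATIONS))
    def test_additivity_per_modification(self, mod):
        core = "TLGCMNGTERCLGLP"  # has Cys pairs and Met, so all mods legal
        base = PeptideProduct(core)
        add, remove = MODIFICATIONS[mod]
        delta = monoisotopic_mass(add) - monoisotopic_mass(remove)
        modded = PeptideProduct(core, mods={mod: 1})
        got = monoisotopic_mass(apply_modifications(modded)) - monoisotopic_mass(
            apply_modifications(base)
        )
        assert math.isclose(got, delta, rel_tol=1e-9, abs_tol=1e-9)

    @pytest.mark.parametrize(
        "core,mods",
        [
            ("GTHLYTITP", {"disulfide": 1}),  # no cysteine pair
            ("GTHLYTITP", {"met_sulfoxide": 1}),  # no methionine
            ("TFCDLATKQCYP", {"disulfide": 1, "cam_cys": 1}),  # overlapping pair
            ("ACA", {"cam_cys": 2}),  # more CAM than Cys
        ],
    )
    def test_chemistry_invariants_enforced(self, core, mods):
        with pytest.raises(ValueError):
            PeptideProduct(core, mods=mods)


class TestIsotopes:
    def test_two_sulfur_peptide_full_label_shift(self):
        # disulfide-bridged TFCDLATKQCYP: exactly two S atoms
        f = apply_modifications(PeptideProduct("TFCDLATKQCYP", mods={"disulfide": 1}))
        assert f["S"] == 2
        shift = isotope_shift(f, IsotopeLabel.from_name("34S"))
        assert nominal_shift(shift) == 4

    def test_three_sulfur_peptide_counts_methionine(self):
        # TLGCMNGTERCLGLP carries 2 Cys + 1 Met = 3 S; a full label adds ~6 Da
        f = apply_modifications(PeptideProduct("TLGCMNGTERCLGLP", mods={"disulfide": 1}))
        assert f["S"] == 3
        assert nominal_shift(isotope_shift(f, IsotopeLabel.from_name("34S"))) == 6

    def test_no_labeled_atoms_gives_zero(self):
        f = ElementalFormula.parse("C5H8")
        assert isotope_shift(f, IsotopeLabel.from_name("15N")) == 0.0

    def test_nitrogen_count_by_independent_residue_oracle(self):
        # N atoms per residue, read off the standard side chains
        n_per_residue = {
            "G": 1, "A": 1, "S": 1, "P": 1, "V": 1, "T": 1, "C": 1, "L": 1,
            "I": 1, "M": 1, "F": 1, "Y": 1, "E": 1, "D": 1, "N": 2, "Q": 2,
            "K": 2, "W": 2, "H": 3, "R": 4,
        }
        label = IsotopeLabel.from_name("15N")
        for core in ("GTHLYTITP", "TLGCMNGTERCLGLP", "APLWDLVRWGAP"):
            expected_n = sum(n_per_residue[a] for a in core)
            shift = isotope_shift(peptide_formula(core, "cyclic"), label)
            assert math.isclose(shift, expected_n * 0.9970348941, rel_tol=1e-9)
        assert peptide_formula("GTHLYTITP", "cyclic")["N"] == 11

    def test_enrichment_scales_shift(self):
        f = ElementalFormula.parse("N2")
        full = isotope_shift(f, IsotopeLabel.from_name("15N"))
        partial = isotope_shift(f, IsotopeLabel.from_name("15N", enrichment=0.5))
        assert math.isclose(partial, full / 2)


class TestInferAtomCount:
    def test_observed_four_dalton_shift_means_two_sulfurs(self):
        res = infer_atom_count(3.99, IsotopeLabel.from_name("34S"))
        assert res.n_atoms == 2 and res.consistent

    def test_zero_shift(self):
        assert infer_atom_count(0.0, IsotopeLabel.from_name("15N")).n_atoms == 0

    def test_exact_multiples_recovered(self):
        for iso in ("15N", "34S"):
            label = IsotopeLabel.from_name(iso)
            for k in range(1, 31):
                res = infer_atom_count(k * label.per_atom_delta, label)
                assert res.n_atoms == k and abs(res.residual) < 1e-9

    @given(
        k=st.integers(0, 40),
        err_frac=st.floats(-0.29, 0.29),
        iso=st.sampled_from(["15N", "34S"]),
    )
    @settings(max_examples=100, deadline=None)
    def test_recovers_planted_count_within_tolerance(self, k, err_frac, iso):
        label = IsotopeLabel.from_name(iso)
        observed = max(0.0, (k + err_frac) * label.per_atom_delta)
        res = infer_atom_count(observed, label)
        assert res.n_atoms == k
        assert res.consistent

    def test_inconsistent_residual_flagged(self):
        label = IsotopeLabel.from_name("34S")
        res = infer_atom_count(2.5 * label.per_atom_delta, label)
        assert not res.consistent

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            infer_atom_count(float("nan"), IsotopeLabel.from_name("15N"))


def _brute_force_search(target, tol_mda, elements, bound):
    """Independent nested-loop enumeration with the same plausibility filter."""
    hits = []
    elements = sorted(elements)
    for combo in cartesian(*[range(bound + 1)] * len(elements)):
        if not any(combo):
            continue
        counts = dict(zip(elements, combo))
        mass = sum(MONOISOTOPIC_MASS[e] * n for e, n in counts.items())
        if abs(mass - target) > tol_mda / 1000.0:
            continue
        c, h, n = counts.get("C", 0), counts.get("H", 0), counts.get("N", 0)
        rdbe = c + 1 + (n - h) / 2
        if rdbe < -0.5 or h > 2 * c + 2 + n:
            continue
        hits.append((counts, mass))
    return hits


class TestFormulaSearch:
    def test_tyrosine_adduct_candidates(self):
        cands = formula_search(84.0311, 50.0, {"C", "H", "O"}, 20)
        names = {str(c.formula) for c in cands}
        assert {"C4H4O2", "C5H8O"} <= names

    def test_signed_deltas_are_target_minus_candidate(self):
        cands = {str(c.formula): c for c in formula_search(84.0311, 50.0,
                                                           {"C", "H", "O"}, 20)}
        assert cands["C4H4O2"].delta_mda > 0 > cands["C5H8O"].delta_mda

    def test_water_found_exactly(self):
        cands = formula_search(18.0106, 1.0, {"H", "O"}, 20)
        assert [str(c.formula) for c in cands] == ["H2O"]

    def test_sorted_by_absolute_delta(self):
        cands = formula_search(84.0311, 50.0, {"C", "H", "O"}, 20)
        deltas = [abs(c.delta_mda) for c in cands]
        assert deltas == sorted(deltas)

    def test_equals_nested_loop_oracle(self):
        ours = formula_search(100.0524, 5.0, {"C", "H", "N", "O"}, 10)
        oracle = _brute_force_search(100.0524, 5.0, {"C", "H", "N", "O"}, 10)
        assert {str(c.formula) for c in ours} == {
            str(ElementalFormula(counts)) for counts, _ in oracle
        }

    @given(target=st.floats(20.0, 250.0), tol=st.floats(1.0, 30.0))
    @settings(max_examples=25, deadline=None)
    def test_oracle_equivalence_randomized(self, target, tol):
        ours = formula_search(target, tol, {"C", "H", "O"}, 12)
        oracle = _brute_force_search(target, tol, {"C", "H", "O"}, 12)
        assert len(ours) == len(oracle)
        assert {str(c.formula) for c in ours} == {
            str(ElementalFormula(counts)) for counts, _ in oracle
        }

    def test_bad_arguments_rejected(self):
        with pytest.raises(ValueError):
            formula_search(100.0, -1.0, {"C"})
        with pytest.raises(ValueError):
            formula_search(100.0, 5.0, set())
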