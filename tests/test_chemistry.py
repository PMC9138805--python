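"""Lipid formula construction and monoisotopic m/z computation."""

import pytest
from hypothesis import given, settings, strategies as st

from lipidmrm.elements import DEUTERIUM_SHIFT, MONOISOTOPIC_MASS
from lipidmrm.formula import ElementFormula, monoisotopic_mass, nominal_mass
from lipidmrm.mz import (
    ADDUCTS,
    NH3_MASS,
    fa_carboxylate_mz,
    formula_of_species,
    free_fatty_acid_formula,
    headgroup_product_mz,
    precursor_mz,
    product_mz_neutral_loss_fa,
)
from lipidmrm.species import FattyAcyl, LipidSpecies, parse_species
from lipidmrm.library_config import default_standards


# -- independent element bookkeeping (test-side oracle) ----------------------

M = MONOISOTOPIC_MASS


def brute_force_glycerolipid(c, d, n_chains):
    """Glycerol + n free acids - n waters, element by element."""
    counts = {"C": 3, "H": 8, "O": 3}
    counts["C"] += c
    counts["H"] += 2 * c - 2 * d
    counts["O"] += 2 * n_chains
    counts["H"] -= 2 * n_chains
    counts["O"] -= n_chains
    return counts


def brute_force_pc(c, d):
    """Glycerophosphocholine backbone + 2 acids - 2 waters."""
    counts = {"C": 8, "H": 20, "N": 1, "O": 6, "P": 1}
    counts["C"] += c
    counts["H"] += 2 * c - 2 * d - 4
    counts["O"] += 4 - 2
    return counts


class TestFormulaOfSpecies:
    def test_pc_38_4_matches_backbone_assembly(self):
        f = formula_of_species(parse_species("PC 38:4"))
        assert dict(f) == brute_force_pc(38, 4)
        assert str(f) == "C46H84NO8P"

    def test_tag_52_6_matches_glycerol_assembly(self):
        f = formula_of_species(parse_species("TAG 52:6"))
        assert dict(f) == brute_force_glycerolipid(52, 6, 3)
        assert str(f) == "C55H94O6"

    def test_sm_d9_label_replaces_nine_hydrogens(self):
        unlabeled = formula_of_species(parse_species("SM(d18:1/18:1)"))
        labeled = formula_of_species(parse_species("SM(d18:1/18:1(d9))"))
        assert str(unlabeled) == "C41H81N2O6P"
        assert str(labeled) == "C41H72D9N2O6P"
        assert labeled == unlabeled.substitute_deuterium(9)

    def test_inconsistent_chains_rejected(self):
        with pytest.raises(ValueError, match="chains sum"):
            LipidSpecies("PC", 38, 4, (FattyAcyl(16, 0), FattyAcyl(18, 1)))


class TestMonoisotopicMass:
    @pytest.mark.parametrize(
        "formula, expected, tol",
        [
            ("H2O", 18.01056, 1e-5),
            ("C46H84NO8P", 809.5934, 5e-4),
            ("C2H3O2", 59.01331, 1e-5),
        ],
    )
    def test_reference_sums(self, formula, expected, tol):
        assert monoisotopic_mass(ElementFormula.parse(formula)) == pytest.approx(
            expected, abs=tol
        )

    def test_formula_subtraction_never_negative(self):
        with pytest.raises(ValueError, match="negative"):
            ElementFormula.parse("CH4") - ElementFormula.parse("H2O")


class TestPrecursorMz:
    @pytest.mark.parametrize(
        "species, expected, tol",
        [
            ("TAG 52:6", 868.74, 0.1),       # [M+NH4]+, printed 868.8
            ("PC 38:4", 868.607, 0.005),     # acetate adduct
            ("Cer(d18:1/17:0)", 552.5, 0.1),
            ("SM(d18:1/18:1(d9))", 738.7, 0.1),
            ("LPC 18:1(d7)", 587.4, 0.1),
            ("PA(15:0/18:1(d7))", 666.5, 0.1),
            ("DAG(15:0/18:1(d7))", 605.5, 0.1),
            ("PC(15:0/18:1(d7))", 811.6, 0.1),
            ("LPE 18:1(d7)", 485.3, 0.1),
            ("PE(15:0/18:1(d7))", 709.6, 0.1),
            ("PG(15:0/18:1(d7))", 740.5, 0.1),
            ("PI(15:0/18:1(d7))", 828.6, 0.1),
            ("PS(15:0/18:1(d7))", 753.5, 0.1),
        ],
    )
    def test_reference_precursors(self, species, expected, tol):
        assert precursor_mz(parse_species(species)) == pytest.approx(expected, abs=tol)

    def test_disallowed_adduct_for_class(self):
        with pytest.raises(ValueError, match="not the panel adduct"):
            precursor_mz(parse_species("PC 38:4"), "M+H")


class TestProductIons:
    @pytest.mark.parametrize(
        "species, lost, expected",
        [
            ("TAG 52:6", FattyAcyl(16, 0), 595.5),  # printed 595.5
            ("DAG(15:0/18:1(d7))", FattyAcyl(15, 0), 346.3),
            ("TAG(15:0/18:1(d7)/15:0)", FattyAcyl(15, 0), 570.5),
        ],
    )
    def test_neutral_loss_products(self, species, lost, expected):
        q3 = product_mz_neutral_loss_fa(parse_species(species), lost)
        assert q3 == pytest.approx(expected, abs=0.1)

    @pytest.mark.parametrize(
        "fa, expected",
        [
            (FattyAcyl(18, 1, 7), 288.3),
            (FattyAcyl(16, 0), 255.23),
            (FattyAcyl(18, 1), 281.25),
        ],
    )
    def test_carboxylate_anions(self, fa, expected):
        assert fa_carboxylate_mz(fa) == pytest.approx(expected, abs=0.05)

    def test_infeasible_loss_rejected(self):
        # losing 22:6 from TAG 40:4 would need negative remaining unsaturation
        with pytest.raises(ValueError, match="realizable"):
            product_mz_neutral_loss_fa(
                LipidSpecies("TAG", 40, 4), FattyAcyl(22, 6)
            )

    def test_neutral_loss_requires_ammonium_adduct(self):
        with pytest.raises(ValueError, match="M\\+NH4"):
            product_mz_neutral_loss_fa(
                parse_species("TAG 52:6"), FattyAcyl(16, 0), adduct="M+H"
            )

    def test_headgroup_fragments(self):
        assert headgroup_product_mz("SM") == pytest.approx(184.073, abs=0.005)
        assert headgroup_product_mz("Cer") == pytest.approx(264.269, abs=0.005)
        assert headgroup_product_mz("CE") == pytest.approx(369.352, abs=0.005)


# -- invariants ---------------------------------------------------------------

sm_species = st.tuples(st.integers(14, 22), st.integers(0, 6)).map(
    lambda t: LipidSpecies("SM", 18 + t[0], 1 + min(t[1], (t[0] - 2) // 2))
)
pc_species = st.tuples(st.integers(28, 44), st.integers(0, 6)).map(
    lambda t: LipidSpecies("PC", t[0], t[1])
)
tag_species = st.tuples(st.integers(42, 66), st.integers(0, 7)).map(
    lambda t: LipidSpecies("TAG", t[0], t[1])
)


@settings(derandomize=True, max_examples=60)
@given(sm=sm_species, pc=pc_species)
def test_nitrogen_rule_parity(sm, pc):
    """SM (two N) protonated ions have odd nominal m/z; PC (one N) even."""
    sm_mh = nominal_mass(formula_of_species(sm)) + 1  # + proton
    pc_mh = nominal_mass(formula_of_species(pc)) + 1
    assert sm_mh % 2 == 1
    assert pc_mh % 2 == 0


@settings(derandomize=True, max_examples=30)
@given(tag=tag_species)
def test_ammonium_vs_proton_adduct_offset(tag):
    m = monoisotopic_mass(formula_of_species(tag))
    delta = (m + ADDUCTS["M+NH4"].delta) - (m + ADDUCTS["M+H"].delta)
    assert delta == pytest.approx(17.02655, abs=1e-4)


@settings(derandomize=True, max_examples=60)
@given(tag=tag_species, k=st.sampled_from([14, 16, 18]), dk=st.integers(0, 2))
def test_neutral_loss_closure(tag, k, dk):
    """Product + lost acid + NH3 reassemble the precursor exactly."""
    lost = FattyAcyl(k, dk)
    c_rem, d_rem = tag.total_carbons - k, tag.total_double_bonds - dk
    if not (c_rem >= 4 and 0 <= d_rem <= (c_rem - 4) // 2):
        return
    q1 = precursor_mz(tag)
    q3 = product_mz_neutral_loss_fa(tag, lost)
    reassembled = q3 + monoisotopic_mass(free_fatty_acid_formula(lost)) + NH3_MASS
    assert reassembled == pytest.approx(q1, abs=1e-9)


def test_deuterium_shift():
    d7 = precursor_mz(parse_species("PA(15:0/18:1(d7))"))
    unlabeled = precursor_mz(parse_species("PA(15:0/18:1)"))
    assert d7 - unlabeled == pytest.approx(7 * 1.0062767, abs=1e-6)
    assert DEUTERIUM_SHIFT == pytest.approx(1.0062767, abs=1e-6)


def test_negative_standards_share_oleate_d7_q3():
    """All eight negative-mode internal standards quantify on Q3 288.3."""
    q3 = fa_carboxylate_mz(FattyAcyl(18, 1, 7))
    negatives = [s for s in default_standards() if s.ion_mode == "negative"]
    assert len(negatives) == 8
    for std in negatives:
        assert std.q3 == pytest.approx(q3, abs=1e-9)
        assert abs(std.q3 - 288.3) < 0.05


@pytest.mark.parametrize(
    "text",
    ["PC 38:4", "TAG 52:6", "Cer(d18:1/17:0)", "SM(d18:1/18:1(d9))",
     "LPC(18:1(d7))", "PA(15:0/18:1(d7))", "TAG(15:0/18:1(d7)/15:0)"],
)
def test_species_text_round_trip(text):
    sp = parse_species(text)
    assert parse_species(str(sp)) == sp
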