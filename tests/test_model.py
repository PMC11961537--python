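"""Core model: canonical forms, masses, validation."""

import itertools

import pytest
from pyteomics import mass as ptmass

import glysubsume as gs
from glysubsume.model import Link, Monosaccharide, Glycan, UNDETERMINED


WATER = ptmass.calculate_mass(formula="H2O")


def test_canonical_form_is_ordering_invariant(texts):
    # same structure declared with residues in a different document order
    shuffled = "\n".join([
        "RES",
        "1b:b-dgal-HEX-1:5",
        "2b:b-dglc-HEX-1:5",
        "3s:n-acetyl",
        "LIN",
        "1:2d(2+1)3n",
        "2:2o(4+1)1d",
    ])
    a = gs.parse_glycoct(texts["F1"])
    b = gs.parse_glycoct(shuffled)
    assert gs.canonical_form(a) == gs.canonical_form(b)
    assert a == b


def test_canonical_form_distinguishes_information_content(glycans):
    forms = {gs.canonical_form(glycans[n])
             for n in ("F1", "T1", "C1", "B1", "R1", "M1", "M2")}
    assert len(forms) == 7


def test_canonical_form_stable_under_reparse(glycans):
    for g in glycans.values():
        again = gs.parse_glycoct(gs.write_glycoct(g))
        assert gs.canonical_form(again) == gs.canonical_form(g)


def test_equality_is_an_equivalence_on_fixture_family(families):
    _, _, (structures, _) = families[0]
    # reflexive + symmetric + transitive via canonical-form partitioning
    for g in structures[:10]:
        assert g == g
    cf = [gs.canonical_form(g) for g in structures]
    for i, j in itertools.combinations(range(min(len(structures), 12)), 2):
        assert (structures[i] == structures[j]) == (cf[i] == cf[j])


@pytest.mark.parametrize("name,formula", [
    ("F1", ["C8H15NO6", "C6H12O6"]),          # GlcNAc + Gal - H2O
    ("M1", ["C6H12O6"]),
    ("GLCNAC", ["C8H15NO6"]),
    ("O1", ["C8H15NO6", "C6H12O6"]),          # GalNAc + Gal - H2O
    ("NG", ["C8H15NO6"] * 4 + ["C6H12O6"] * 5 + ["C11H19NO9"] * 2),
])
def test_underivatized_mass_matches_formula_arithmetic(glycans, name, formula):
    expected = sum(ptmass.calculate_mass(formula=f) for f in formula) \
        - (len(formula) - 1) * WATER
    assert gs.underivatized_mass(glycans[name]).monoisotopic_da == \
        pytest.approx(expected, abs=1e-6)


def test_f1_weight_class_key(glycans):
    assert gs.underivatized_mass(glycans["F1"]).weight_class_key == 383.14


def test_information_removal_is_mass_preserving(glycans):
    for name in ("F1", "NG", "O2", "R1"):
        g = glycans[name]
        m = gs.underivatized_mass(g).monoisotopic_da
        for op in (gs.topology_of, gs.composition_of, gs.basecomposition_of):
            assert gs.underivatized_mass(op(g)).monoisotopic_da == \
                pytest.approx(m, abs=1e-9)
        if g.root is not UNDETERMINED:
            assert gs.underivatized_mass(
                gs.archetype_of(g)).monoisotopic_da == pytest.approx(m, abs=1e-9)


def test_alditol_adds_two_hydrogens(glycans):
    delta = gs.underivatized_mass(glycans["R1"]).monoisotopic_da \
        - gs.underivatized_mass(glycans["F1"]).monoisotopic_da
    assert round(delta, 2) == 2.02
    assert delta == pytest.approx(ptmass.calculate_mass(formula="H2"), abs=1e-6)


def test_stereochemistry_never_changes_mass(glycans):
    assert gs.underivatized_mass(glycans["M1"]).monoisotopic_da == \
        pytest.approx(gs.underivatized_mass(glycans["M2"]).monoisotopic_da)
    for name in ("T1", "C1", "B1"):
        assert gs.underivatized_mass(glycans[name]).weight_class_key == 383.14


def test_unknown_substituent_is_rejected():
    m = Monosaccharide(superclass="HEX",
                       substituents=(("mystery-group", 2, "dn"),))
    with pytest.raises(gs.UnsupportedComponentError):
        gs.underivatized_mass(Glycan(residues=(m,)))


def test_validate_accepts_fixtures(glycans):
    for g in glycans.values():
        assert gs.validate(g) == []


def test_validate_reports_cycle():
    hexose = Monosaccharide(superclass="HEX")
    g = Glycan(residues=(hexose, hexose),
               links=(Link(parents=frozenset({0}), child=1),
                      Link(parents=frozenset({1}), child=0)),
               root=0)
    assert any(v.startswith("cycle") or v.startswith("multiparent") or
               v.startswith("root") for v in gs.validate(g))
    with pytest.raises(gs.GlycanValidationError):
        gs.canonical_form(g)


def test_validate_reports_disconnected():
    hexose = Monosaccharide(superclass="HEX")
    g = Glycan(residues=(hexose, hexose, hexose),
               links=(Link(parents=frozenset({0}), child=1),),
               root=0)
    assert any(v.startswith("disconnected") for v in gs.validate(g))
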