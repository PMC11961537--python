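"""OBO export and restriction subsets."""

import io

import obonet
import pytest

import glysubsume as gs
from glysubsume.ontology import CATEGORY_INSTANCES


@pytest.fixture(scope="module")
def chain_dag(glycans):
    return gs.build_dag(
        [glycans[n] for n in ("F1", "T1", "C1", "B1")],
        accessions=["GF1", "GT1", "GC1", "GB1"])


@pytest.fixture(scope="module")
def chain_obo(chain_dag):
    return gs.emit_obo(chain_dag)


def test_obo_parses_with_independent_reader(chain_obo):
    graph = obonet.read_obo(io.StringIO(chain_obo))
    assert "GNO:GF1" in graph.nodes


def test_obo_has_five_category_instances(chain_obo):
    assert chain_obo.count("[Instance]") == 5
    for iid in CATEGORY_INSTANCES.values():
        assert f"id: {iid}" in chain_obo


def test_is_a_follows_minimal_mass_preserving_edges(chain_obo):
    graph = obonet.read_obo(io.StringIO(chain_obo))
    assert graph.nodes["GNO:GF1"]["is_a"] == ["GNO:GT1"]
    assert graph.nodes["GNO:GT1"]["is_a"] == ["GNO:GC1"]
    assert graph.nodes["GNO:GC1"]["is_a"] == ["GNO:GB1"]
    # the top of the chain attaches to its molecular-weight class term
    (top,) = graph.nodes["GNO:GB1"]["is_a"]
    assert "383.14" in graph.nodes[top]["name"]


def test_level_shortcut_annotations(chain_obo):
    graph = obonet.read_obo(io.StringIO(chain_obo))
    props = graph.nodes["GNO:GF1"]["property_value"]
    assert "GNO:has_topology GNO:GT1" in props
    assert "GNO:has_composition GNO:GC1" in props
    assert "GNO:has_basecomposition GNO:GB1" in props
    assert 'GNO:has_glytoucan_id "GF1" xsd:string' in props


def test_is_subsumed_by_includes_non_mass_preserving(glycans):
    dag = gs.build_dag([glycans[n] for n in ("T1", "R1")],
                       accessions=["GT1", "GR1"])
    obo = gs.emit_obo(dag)
    graph = obonet.read_obo(io.StringIO(obo))
    props = graph.nodes["GNO:GR1"].get("property_value", [])
    assert "GNO:is_subsumed_by GNO:GT1" in props
    # but the non-mass-preserving edge is not a subClassOf edge
    assert "GNO:GT1" not in graph.nodes["GNO:GR1"]["is_a"]


def test_obsolete_terms(glycans):
    dag = gs.build_dag([glycans["F1"]], accessions=["GF1"],
                       obsolete={"GOLD": "GF1", "GGONE": None})
    obo = gs.emit_obo(dag)
    graph = obonet.read_obo(io.StringIO(obo))
    # obonet drops obsolete terms by default; check the text directly
    assert "id: GNO:GOLD\nname: obsolete glycan GOLD\nis_obsolete: true\n" \
        "replaced_by: GNO:GF1" in obo
    assert "id: GNO:GGONE" in obo
    assert "GNO:GOLD" not in graph.nodes


def test_output_is_deterministic(chain_dag, chain_obo):
    assert gs.emit_obo(chain_dag) == chain_obo


def test_scores_annotated(chain_obo):
    assert 'GNO:has_structure_characterization_score "0" xsd:float' in chain_obo
    assert 'GNO:has_structure_characterization_score "10000" xsd:float' \
        in chain_obo


# ---------------------------------------------------------------------------
# restrictions

def test_restriction_adds_derived_forms(chain_dag):
    r = gs.make_restriction(chain_dag, ["GF1"])
    assert set(r.nodes) == {"GF1", "GT1", "GC1", "GB1"}
    assert r.restriction_members == frozenset({"GF1"})
    obo = gs.emit_obo(r)
    assert 'GNO:is_restriction_member "true" xsd:boolean' in obo
    assert 'GNO:is_restriction_member "false" xsd:boolean' in obo


def test_restriction_infers_direct_edges_by_transitivity(glycans):
    chain = [glycans["F1"], gs.topology_of(glycans["F1"]),
             gs.composition_of(glycans["F1"]),
             gs.basecomposition_of(glycans["F1"])]
    dag = gs.build_dag(chain, accessions=["A", "B", "C", "D"])
    r = gs.make_restriction(dag, ["A", "D"], include_derived_forms=False)
    assert set(r.nodes) == {"A", "D"}
    assert {e.pair() for e in r.edges} == {("D", "A")}


def test_restriction_closure_soundness(chain_dag):
    r = gs.make_restriction(chain_dag, ["GF1", "GB1"],
                            include_derived_forms=False)
    retained = set(r.nodes)
    induced = {(u, v) for u, v in chain_dag.closure()
               if u in retained and v in retained}
    assert r.closure() == induced


def test_restriction_errors(chain_dag):
    with pytest.raises(gs.RestrictionError):
        gs.make_restriction(chain_dag, [])
    with pytest.raises(gs.RestrictionError) as err:
        gs.make_restriction(chain_dag, ["NOPE"])
    assert "NOPE" in str(err.value)
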