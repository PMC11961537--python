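"""OBO-format export of the subsumption DAG and restriction subsets.

The emitted ontology mirrors the GNOme predicate vocabulary: ``is_a``
(subClassOf) carries the primary, mass-preserving subsumption edges;
``is_subsumed_by`` additionally carries non-mass-preserving edges (the
alditol-reduced reducing-end relationships); structures are annotated with
their accession, characterization category and score, the topology /
composition / base-composition forms when those exist in the DAG, and
composition-string synonyms.  Structures with no subsumer attach to a
molecular-weight class term (labeled with the 2-decimal mass), all of which
sit under a single root ``glycan`` class.  Five named instances represent
the subsumption categories.  Output is deterministic: byte-identical runs
on identical input.

Restrictions retain a member subset plus each member's archetype,
topology, composition and base-composition forms present in the primary
DAG; direct subsumption between retained structures is inferred by
transitivity from the primary ontology, and members are flagged with
``is_restriction_member``.
"""

from __future__ import annotations

from collections import defaultdict

import networkx as nx

from .levels import (
    NotApplicableError, archetype_of, basecomposition_of, category_of,
    composition_of, topology_of,
)
from .model import Glycan, GlycanError, canonical_form, underivatized_mass
from .naming import composition_name
from .scoring import characterization_score
from .subsumption import SubsumptionDAG, SubsumptionEdge, transitive_reduction

__all__ = ["emit_obo", "make_restriction", "RestrictionError",
           "ManifestError", "CATEGORY_INSTANCES"]


class ManifestError(GlycanError):
    """A structure lacks the accession needed to mint its term."""


class RestrictionError(GlycanError):
    """Restriction members are empty or do not resolve."""


_ROOT_ID = "GNO:00000001"
_CATEGORY_CLASS_ID = "GNO:00000002"

#: Deterministic ids for the 5 subsumption-category named instances.
CATEGORY_INSTANCES = {
    "Saccharide": "GNO:00000101",
    "Topology": "GNO:00000102",
    "Composition": "GNO:00000103",
    "BaseComposition": "GNO:00000104",
    "MolecularWeight": "GNO:00000105",
}

_TYPEDEFS = (
    "is_subsumed_by",
    "has_glytoucan_id",
    "has_glytoucan_link",
    "has_subsumption_category",
    "has_topology",
    "has_composition",
    "has_basecomposition",
    "has_Byonic_name",
    "has_structure_characterization_score",
    "is_restriction_member",
    "has_structure_browser_link",
    "has_composition_browser_link",
)

_GLYTOUCAN_URL = "https://glytoucan.org/Structures/Glycans/"


def _term_id(accession: str) -> str:
    return f"GNO:{accession}"


def emit_obo(dag: SubsumptionDAG, *, ontology_name: str = "gno-local",
             browser_base: str = None) -> str:
    """Render ``dag`` as an OBO 1.2 flat file (returned as a string).

    Browser deep-link predicates are emitted only when ``browser_base``
    supplies a base URL.  Obsolete accessions recorded on the DAG become
    obsolete terms pointing at their replacement where known.
    """
    for nid in dag.nodes:
        if not nid:
            raise ManifestError("every node needs an accession")

    lines = ["format-version: 1.2", f"ontology: {ontology_name}", ""]
    for name in _TYPEDEFS:
        lines += ["[Typedef]", f"id: GNO:{name}", f"name: {name}", ""]

    lines += ["[Term]", f"id: {_ROOT_ID}", "name: glycan", ""]
    lines += ["[Term]", f"id: {_CATEGORY_CLASS_ID}",
              "name: subsumption category", ""]
    for cat in ("Saccharide", "Topology", "Composition", "BaseComposition",
                "MolecularWeight"):
        lines += ["[Instance]", f"id: {CATEGORY_INSTANCES[cat]}",
                  f"name: {cat}", f"instance_of: {_CATEGORY_CLASS_ID}", ""]

    # molecular-weight class terms, numbered by ascending mass
    wc_ids = {}
    for i, key in enumerate(sorted(dag.weight_classes), start=1):
        wc_ids[key] = f"GNO:{1000 + i:08d}"
        lines += ["[Term]", f"id: {wc_ids[key]}",
                  f"name: glycan of molecular weight {key:.2f} Da",
                  f"is_a: {_ROOT_ID}", ""]

    node_wc = {}
    for key, nids in dag.weight_classes.items():
        for nid in nids:
            node_wc[nid] = key

    by_cf = {canonical_form(g): nid for nid, g in dag.nodes.items()}
    mp_parents = defaultdict(list)
    all_parents = defaultdict(list)
    for e in dag.edges:
        all_parents[e.subsumed].append(e.subsumer)
        if e.mass_preserving:
            mp_parents[e.subsumed].append(e.subsumer)

    members = dag.restriction_members

    for nid in sorted(dag.nodes):
        g = dag.nodes[nid]
        term = ["[Term]", f"id: {_term_id(nid)}"]
        byonic = composition_name(g, "byonic")
        term.append(f"name: {byonic if byonic else f'glycan {nid}'}")
        parents = sorted(mp_parents.get(nid, ()))
        if parents:
            term += [f"is_a: {_term_id(p)}" for p in parents]
        else:
            key = node_wc.get(
                nid, underivatized_mass(g).weight_class_key)
            if key in wc_ids:
                term.append(f"is_a: {wc_ids[key]}")
            else:
                term.append(f"is_a: {_ROOT_ID}")
        if byonic:
            term.append(f'synonym: "{byonic}" EXACT []')
            term.append(
                f'property_value: GNO:has_Byonic_name "{byonic}" xsd:string')
        term.append(
            f'property_value: GNO:has_glytoucan_id "{nid}" xsd:string')
        if not nid.startswith("SYN"):
            term.append(
                f'property_value: GNO:has_glytoucan_link '
                f'"{_GLYTOUCAN_URL}{nid}" xsd:anyURI')
        cat = category_of(g)
        term.append(f"property_value: GNO:has_subsumption_category "
                    f"{CATEGORY_INSTANCES[cat.name]}")
        score = characterization_score(g)
        term.append(f'property_value: '
                    f'GNO:has_structure_characterization_score '
                    f'"{score:g}" xsd:float')
        for pred, op in (("has_topology", topology_of),
                         ("has_composition", composition_of),
                         ("has_basecomposition", basecomposition_of)):
            derived_cf = canonical_form(op(g))
            target = by_cf.get(derived_cf)
            if target is not None:
                term.append(f"property_value: GNO:{pred} {_term_id(target)}")
        for p in sorted(all_parents.get(nid, ())):
            term.append(
                f"property_value: GNO:is_subsumed_by {_term_id(p)}")
        if browser_base:
            term.append(f'property_value: GNO:has_structure_browser_link '
                        f'"{browser_base}#focus={nid}" xsd:anyURI')
        if members is not None:
            flag = "true" if nid in members else "false"
            term.append(f'property_value: GNO:is_restriction_member '
                        f'"{flag}" xsd:boolean')
        lines += term + [""]

    for acc in sorted(dag.obsolete):
        repl = dag.obsolete[acc]
        term = ["[Term]", f"id: {_term_id(acc)}",
                f"name: obsolete glycan {acc}", "is_obsolete: true"]
        if repl:
            term.append(f"replaced_by: {_term_id(repl)}")
        lines += term + [""]

    return "\n".join(lines)


def make_restriction(dag: SubsumptionDAG, members,
                     include_derived_forms: bool = True) -> SubsumptionDAG:
    """Restrict ``dag`` to ``members`` plus their derived forms.

    Retains the member structures together with their archetype, topology,
    composition and base-composition forms when present in the primary
    DAG; edges are the transitive reduction of the primary closure induced
    on the retained nodes (so direct relationships between distant members
    are inferred by transitivity).  The returned DAG carries
    ``restriction_members``.
    """
    members = frozenset(members)
    if not members:
        raise RestrictionError("restriction member set is empty")
    unknown = sorted(members - set(dag.nodes))
    if unknown:
        raise RestrictionError(
            f"unknown accessions in restriction: {', '.join(unknown)}")

    by_cf = {canonical_form(g): nid for nid, g in dag.nodes.items()}
    retained = set(members)
    if include_derived_forms:
        for nid in members:
            g = dag.nodes[nid]
            derived = [topology_of(g), composition_of(g),
                       basecomposition_of(g)]
            try:
                derived.append(archetype_of(g))
            except NotApplicableError:
                pass
            for d in derived:
                target = by_cf.get(canonical_form(d))
                if target is not None:
                    retained.add(target)

    closure_all = dag.closure()
    closure_mp = dag.closure(mass_preserving_only=True)
    induced = [(u, v) for u, v in closure_all
               if u in retained and v in retained]
    reduced = transitive_reduction(
        SubsumptionEdge(u, v, mass_preserving=(u, v) in closure_mp)
        for u, v in induced)

    weight_classes = {
        key: tuple(nid for nid in nids if nid in retained)
        for key, nids in dag.weight_classes.items()}
    weight_classes = {k: v for k, v in weight_classes.items() if v}
    return SubsumptionDAG(
        nodes={nid: dag.nodes[nid] for nid in sorted(retained)},
        edges=frozenset(reduced),
        weight_classes=weight_classes,
        synonyms={nid: dag.synonyms.get(nid, ()) for nid in retained},
        obsolete=dict(dag.obsolete),
        restriction_members=members)
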