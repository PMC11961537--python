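"""Pairwise glycan subsumption and the transitive-reduced subsumption DAG.

Glycan ``a`` subsumes glycan ``b`` (``a ⊃ b``) when ``a`` is a less
characterized description consistent with ``b``.  The decision enumerates
subsumption-aware perfect matchings between the monosaccharides of the two
structures with a backtracking search; when both operands carry links, each
link of the subsumed structure must in turn be subsumed by a distinct link
of the subsumer, while undetermined subsumer links may remain unmatched.
Compositions short-circuit the link check: a composition subsumes anything
its residues match, and is never subsumed by a non-composition.  Floating
substituents of the subsumer may match substituents attached to residues of
the subsumed structure.

Collections are organized by first grouping structures by molecular weight
(to two decimals), computing all pairwise relationships within each group,
and removing every relationship implied by transitivity.  Alditol-reduced
reducing-end structures are redundantly added to the weight group of their
unreduced counterparts so that non-mass-preserving subsumption edges can be
drawn from unreduced structures with an undetermined reducing-end anomer.
"""

from __future__ import annotations

import itertools
import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import networkx as nx

from .model import (
    UNDETERMINED, UNDET, Glycan, GlycanError, H2_MASS, Link, Monosaccharide,
    canonical_form, underivatized_mass, validate, GlycanValidationError,
)

__all__ = [
    "SubsumptionEdge", "SubsumptionDAG",
    "mono_subsumes", "link_subsumes", "subsumes",
    "group_by_mw", "pairwise_edges", "transitive_reduction", "build_dag",
    "WeightGroupError", "SubsumptionConsistencyError",
]


class WeightGroupError(GlycanError):
    """Subsumption requested across different molecular-weight classes."""


class SubsumptionConsistencyError(GlycanError):
    """A cycle among non-isomorphic structures (antisymmetry violation)."""


@dataclass(frozen=True)
class SubsumptionEdge:
    """Directed edge: ``subsumer`` is the less characterized structure."""

    subsumer: str
    subsumed: str
    mass_preserving: bool = True

    def pair(self):
        return (self.subsumer, self.subsumed)


# ---------------------------------------------------------------------------
# residue-level subsumption

def _match_substituents(ma: Monosaccharide, mb: Monosaccharide):
    """Match ``ma``'s substituents injectively into ``mb``'s.

    Substituents pair by (name, linkage-type); an undetermined position on
    the subsumer side matches any position, a determined one only its equal.
    Returns the tuple of names of ``mb``'s substituents left unmatched, or
    ``None`` when ``ma`` has a substituent that cannot be placed.
    """
    bgroups = defaultdict(list)
    for name, pos, ltype in mb.substituents:
        bgroups[(name, ltype)].append(pos)
    agroups = defaultdict(list)
    for name, pos, ltype in ma.substituents:
        agroups[(name, ltype)].append(pos)
    leftover = []
    for key, apos in agroups.items():
        avail = Counter(bgroups.pop(key, []))
        undet = 0
        for p in apos:
            if p is UNDETERMINED:
                undet += 1
            elif avail[p] > 0:
                avail[p] -= 1
            else:
                return None
        remaining = sum(avail.values())
        if undet > remaining:
            return None
        leftover.extend([key[0]] * (remaining - undet))
    for (name, _), poslist in bgroups.items():
        leftover.extend([name] * len(poslist))
    return tuple(leftover)


def _mono_match(ma: Monosaccharide, mb: Monosaccharide, *,
                exclude_reducing_end: bool = False):
    """Core residue comparison; returns leftover substituent names or None.

    With ``exclude_reducing_end`` the anomeric, ring and alditol state of
    the pair is ignored (used when relating unreduced and alditol-reduced
    reducing ends).
    """
    if ma.superclass != mb.superclass:
        return None
    if ma.stereo and ma.stereo != mb.stereo:
        return None
    if exclude_reducing_end:
        mods_a = tuple(m for m in ma.modifications if m[1] != "aldi")
        mods_b = tuple(m for m in mb.modifications if m[1] != "aldi")
        if mods_a != mods_b:
            return None
    else:
        if ma.modifications != mb.modifications:
            return None
        if ma.ring is not UNDETERMINED and ma.ring != mb.ring:
            return None
        if ma.anomer != UNDET and ma.anomer != mb.anomer:
            return None
    return _match_substituents(ma, mb)


def mono_subsumes(ma: Monosaccharide, mb: Monosaccharide) -> bool:
    """True iff residue description ``ma`` subsumes ``mb``.

    Requires equal superclass and modification multisets (so the relation
    is mass-preserving), with every determined feature of ``ma`` present
    and equal in ``mb`` and substituent multisets equal by name and
    linkage-type (positions may be undetermined on the subsumer side only).
    """
    return _mono_match(ma, mb) == ()


def link_subsumes(la: Link, lb: Link, match) -> bool:
    """True iff link ``la`` of the subsumer subsumes ``lb`` of the subsumed
    under the residue ``match`` (a mapping of subsumer residue indices to
    subsumed residue indices)."""
    if match[la.child] != lb.child:
        return False
    mapped_parents = {match[p] for p in la.parents}
    if not set(lb.parents) <= mapped_parents:
        return False
    if la.parent_positions is not UNDETERMINED:
        if lb.parent_positions is UNDETERMINED:
            return False
        if not lb.parent_positions <= la.parent_positions:
            return False
    if la.child_position is not UNDETERMINED:
        if la.child_position != lb.child_position:
            return False
    if la.parent_type != lb.parent_type or la.child_type != lb.child_type:
        return False
    return True


# ---------------------------------------------------------------------------
# structure-level subsumption

def _links_match(a: Glycan, b: Glycan, mapping) -> bool:
    """Every link of ``b`` subsumed by a distinct link of ``a``; unmatched
    links of ``a`` are permitted only when undetermined."""
    alinks = list(a.links)

    def bt(k, used):
        if k == len(b.links):
            return all(alinks[i].undetermined
                       for i in range(len(alinks)) if i not in used)
        lb = b.links[k]
        for i, la in enumerate(alinks):
            if i in used:
                continue
            if link_subsumes(la, lb, mapping) and bt(k + 1, used | {i}):
                return True
        return False

    return bt(0, frozenset())


def _reduced_end_index(g: Glycan):
    """Index of the single alditol-bearing residue, or None."""
    idx = [i for i, m in enumerate(g.residues) if m.has_aldi]
    if len(idx) != 1:
        return None
    if g.root is not UNDETERMINED and g.root != idx[0]:
        return None
    return idx[0]


def subsumes(a: Glycan, b: Glycan, *, reduced_pair: bool = False) -> bool:
    """Decide ``a ⊃ b`` (reflexively: every glycan subsumes itself).

    Both operands must belong to the same molecular-weight class unless
    ``reduced_pair`` flags a comparison between an unreduced structure
    ``a`` (whose reducing-end anomer must be undetermined) and an
    alditol-reduced structure ``b``; in that case the reducing-end pair's
    anomeric, ring and alditol state is excluded from the comparison.
    """
    if not reduced_pair:
        ka = underivatized_mass(a).weight_class_key
        kb = underivatized_mass(b).weight_class_key
        if ka != kb:
            raise WeightGroupError(
                f"structures belong to different weight classes "
                f"({ka} vs {kb}); group first")
    if len(a.residues) != len(b.residues):
        return False
    excluded_b = None
    if reduced_pair:
        excluded_b = _reduced_end_index(b)
        if excluded_b is None:
            raise WeightGroupError(
                "reduced_pair comparison requires an alditol-reduced "
                "subsumed structure")
    if b.is_composition and not a.is_composition:
        return False
    # cheap invariants: superclasses and total substituent names must agree
    if Counter(m.superclass for m in a.residues) != \
            Counter(m.superclass for m in b.residues):
        return False
    subs_a = Counter(s[0] for m in a.residues for s in m.substituents)
    subs_a.update(a.floating_substituents)
    subs_b = Counter(s[0] for m in b.residues for s in m.substituents)
    subs_b.update(b.floating_substituents)
    if subs_a != subs_b:
        return False

    forced = {}
    if not a.is_composition and not b.is_composition:
        forced[a.root] = b.root
        if reduced_pair:
            if b.root != excluded_b:
                return False
            if a.residues[a.root].anomer != UNDET or a.residues[a.root].has_aldi:
                return False

    # candidate subsumed residues for every subsumer residue
    n = len(a.residues)
    options = []
    for i, ma in enumerate(a.residues):
        opts = {}
        for j, mb in enumerate(b.residues):
            if i in forced and forced[i] != j:
                continue
            if forced and i not in forced and j in forced.values():
                continue
            excl = reduced_pair and j == excluded_b
            if excl and i not in forced:
                # a composition subsumer: the residue standing in for the
                # reducing end must itself have an undetermined anomer
                if ma.anomer != UNDET or ma.has_aldi:
                    continue
            leftover = _mono_match(ma, mb, exclude_reducing_end=excl)
            if leftover is not None:
                opts[j] = leftover
        if not opts:
            return False
        options.append((len(opts), i, opts))
    options.sort()

    order = [i for _, i, _ in options]
    opts_by_res = {i: o for _, i, o in options}
    float_b = Counter(b.floating_substituents)
    float_a = Counter(a.floating_substituents)

    def bt(k, used, mapping, leftovers):
        if k == n:
            pool = Counter(leftovers)
            pool.update(float_b)
            if pool != float_a:
                return False
            if a.is_composition:
                return True
            return _links_match(a, b, mapping)
        i = order[k]
        for j, leftover in opts_by_res[i].items():
            if j in used:
                continue
            mapping[i] = j
            if bt(k + 1, used | {j}, mapping, leftovers + list(leftover)):
                return True
            del mapping[i]
        return False

    return bt(0, frozenset(), {}, [])


# ---------------------------------------------------------------------------
# collections

def group_by_mw(structures):
    """Group structures by molecular-weight class key.

    Returns a mapping ``key -> list of (glycan, redundant_alditol)``.
    Every structure appears unflagged in its own class; an alditol-reduced
    reducing-end structure is redundantly added, flagged, to the class of
    its unreduced counterpart (its mass minus H2).
    """
    groups = defaultdict(list)
    for g in structures:
        violations = validate(g)
        if violations:
            raise GlycanValidationError(violations)
        key = underivatized_mass(g).weight_class_key
        groups[key].append((g, False))
        if _reduced_end_index(g) is not None:
            unreduced_key = round(underivatized_mass(g).monoisotopic_da
                                  - H2_MASS, 2)
            groups[unreduced_key].append((g, True))
    return dict(groups)


def pairwise_edges(group):
    """All pairwise subsumption edges within one weight group.

    ``group`` is a list of ``(glycan, redundant_alditol)`` pairs (as
    produced by :func:`group_by_mw`) or of bare glycans.  Isomorphic
    duplicates collapse to a single node.  Edges are returned over node
    ids, which are the structures' canonical forms; cross pairs between a
    native structure and a redundantly added alditol structure yield
    non-mass-preserving edges.
    """
    entries = []
    seen = {}
    for item in group:
        g, flag = item if isinstance(item, tuple) else (item, False)
        cf = canonical_form(g)
        if (cf, flag) in seen:
            continue
        seen[(cf, flag)] = True
        entries.append((cf, g, flag))
    edges = set()
    for (ca, ga, fa), (cb, gb, fb) in itertools.permutations(entries, 2):
        if ca == cb:
            continue
        if fa:
            continue        # a reduced structure never subsumes unreduced
        if not fa and not fb:
            if subsumes(ga, gb):
                edges.add(SubsumptionEdge(ca, cb, mass_preserving=True))
        elif fb:
            if subsumes(ga, gb, reduced_pair=True):
                edges.add(SubsumptionEdge(ca, cb, mass_preserving=False))
    return edges


def transitive_reduction(edges):
    """Minimal edge set with the same transitive closure.

    ``edges`` may be :class:`SubsumptionEdge` objects or bare ``(u, v)``
    pairs.  Raises :class:`SubsumptionConsistencyError` on cycles.
    """
    norm = []
    for e in edges:
        if isinstance(e, SubsumptionEdge):
            norm.append(e)
        else:
            norm.append(SubsumptionEdge(e[0], e[1]))
    graph = nx.DiGraph()
    graph.add_edges_from(e.pair() for e in norm)
    if not nx.is_directed_acyclic_graph(graph):
        raise SubsumptionConsistencyError(
            "subsumption edges contain a cycle among distinct structures")
    reduced = nx.transitive_reduction(graph)
    flags = {}
    for e in norm:
        flags[e.pair()] = e.mass_preserving
    return {SubsumptionEdge(u, v, mass_preserving=flags[(u, v)])
            for u, v in reduced.edges}


@dataclass
class SubsumptionDAG:
    """Transitive-reduced subsumption DAG over a structure collection.

    ``nodes`` maps node id to its glycan; ``edges`` is the minimal edge
    set (mass-preserving and non-mass-preserving, flagged); weight classes
    key node ids by 2-decimal monoisotopic mass; ``synonyms`` carries all
    accessions collapsed into a node; ``obsolete`` maps retired accessions
    to their replacement (or None); ``restriction_members`` is set on
    restricted DAGs only.
    """

    nodes: dict
    edges: frozenset
    weight_classes: dict
    synonyms: dict = field(default_factory=dict)
    obsolete: dict = field(default_factory=dict)
    restriction_members: frozenset = None

    def subsumers_of(self, node_id, *, mass_preserving_only=False):
        return sorted(e.subsumer for e in self.edges if e.subsumed == node_id
                      and (e.mass_preserving or not mass_preserving_only))

    def graph(self, *, mass_preserving_only=False) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(e.pair() for e in self.edges
                         if e.mass_preserving or not mass_preserving_only)
        return g

    def closure(self, *, mass_preserving_only=False) -> set:
        return {(u, v) for u, v in
                nx.transitive_closure_dag(
                    self.graph(mass_preserving_only=mass_preserving_only)
                ).edges}

    def to_json(self) -> str:
        from .glycoct import write_glycoct
        payload = {
            "nodes": {nid: {"glycoct": write_glycoct(g),
                            "synonyms": sorted(self.synonyms.get(nid, ()))}
                      for nid, g in sorted(self.nodes.items())},
            "edges": sorted(
                [{"subsumer": e.subsumer, "subsumed": e.subsumed,
                  "mass_preserving": e.mass_preserving} for e in self.edges],
                key=lambda d: (d["subsumer"], d["subsumed"])),
            "weight_classes": {f"{k:.2f}": sorted(v)
                               for k, v in sorted(self.weight_classes.items())},
            "obsolete": {k: v for k, v in sorted(self.obsolete.items())},
        }
        if self.restriction_members is not None:
            payload["restriction_members"] = sorted(self.restriction_members)
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SubsumptionDAG":
        from .glycoct import parse_glycoct
        payload = json.loads(text)
        nodes = {nid: parse_glycoct(entry["glycoct"], name=nid)
                 for nid, entry in payload["nodes"].items()}
        edges = frozenset(
            SubsumptionEdge(e["subsumer"], e["subsumed"],
                            mass_preserving=e["mass_preserving"])
            for e in payload["edges"])
        wcs = {float(k): tuple(v)
               for k, v in payload["weight_classes"].items()}
        synonyms = {nid: tuple(entry.get("synonyms", ()))
                    for nid, entry in payload["nodes"].items()}
        members = payload.get("restriction_members")
        return cls(nodes=nodes, edges=edges, weight_classes=wcs,
                   synonyms=synonyms,
                   obsolete=payload.get("obsolete", {}),
                   restriction_members=(frozenset(members)
                                        if members is not None else None))


def build_dag(structures, accessions=None, obsolete=None) -> SubsumptionDAG:
    """Build the transitive-reduced subsumption DAG for a collection.

    ``accessions`` optionally parallels ``structures``; isomorphic
    duplicates collapse to one node whose id is the lexicographically first
    accession (synthetic ids ``SYNnnnn``, assigned in canonical-form order,
    are used where no accession is given).  ``obsolete`` is a mapping of
    retired accession -> replacement accession (or None), carried through
    to the ontology export.
    """
    if accessions is not None and len(accessions) != len(structures):
        raise GlycanError("accessions must parallel structures")
    by_cf = {}
    acc_by_cf = defaultdict(list)
    for k, g in enumerate(structures):
        violations = validate(g)
        if violations:
            raise GlycanValidationError(violations)
        cf = canonical_form(g)
        by_cf.setdefault(cf, g)
        if accessions is not None and accessions[k]:
            acc_by_cf[cf].append(accessions[k])

    ids = {}
    synonyms = {}
    syn_counter = 0
    for cf in sorted(by_cf):
        accs = sorted(set(acc_by_cf.get(cf, ())))
        if accs:
            ids[cf] = accs[0]
        else:
            syn_counter += 1
            ids[cf] = f"SYN{syn_counter:04d}"
        synonyms[ids[cf]] = tuple(accs)

    nodes = {ids[cf]: g for cf, g in by_cf.items()}
    weight_classes = defaultdict(list)
    all_edges = set()
    groups = group_by_mw(list(by_cf.values()))
    for key, group in sorted(groups.items()):
        for g, flag in group:
            if not flag:
                weight_classes[key].append(ids[canonical_form(g)])
        for e in pairwise_edges(group):
            all_edges.add(SubsumptionEdge(ids[e.subsumer], ids[e.subsumed],
                                          mass_preserving=e.mass_preserving))
    edges = frozenset(transitive_reduction(all_edges))
    return SubsumptionDAG(
        nodes=nodes, edges=edges,
        weight_classes={k: tuple(sorted(v))
                        for k, v in weight_classes.items()},
        synonyms=synonyms, obsolete=dict(obsolete or {}))
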