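"""Characterization levels: category assignment and level operations.

Five categories order glycan descriptions from most to least characterized:
Saccharide, Topology, Composition, BaseComposition, MolecularWeight.
Which category a structure belongs to is driven purely by the presence or
absence of structural information:

* anomeric configurations or determined glycosidic attachment carbons
  (parent-side link positions) -> Saccharide;
* otherwise inter-residue links or determined ring forms -> Topology;
* otherwise any stereochemistry -> Composition;
* otherwise -> BaseComposition.

MolecularWeight is reserved for molecular-weight class terms in the
ontology and is never assigned to a concrete structure.

Each of Topology, Composition and BaseComposition is also an *operation*
that strips exactly the information not relevant to the level; a structure
unchanged by the operation belongs to that level.  The Archetype operation
removes only the reducing-end residue's anomeric and ring information,
collapsing redundancy in reducing-end characterization.

An alditol-reduced reducing end is chemically fixed open-chain, so ``aldi``
counts as determined anomeric and ring state: level operations leave it in
place (they are all mass-preserving) and a reduced structure is its own
archetype.
"""

from __future__ import annotations

import enum
from dataclasses import replace

from .model import (
    UNDETERMINED, UNDET, Glycan, GlycanError, Link, Monosaccharide,
)

__all__ = ["SubsumptionCategory", "category_of", "topology_of",
           "composition_of", "basecomposition_of", "archetype_of",
           "NotApplicableError"]


class NotApplicableError(GlycanError):
    """The operation does not apply to this kind of glycan."""


class SubsumptionCategory(enum.Enum):
    """Characterization-level category; rank 0 is most characterized."""

    Saccharide = 0
    Topology = 1
    Composition = 2
    BaseComposition = 3
    MolecularWeight = 4

    @property
    def rank(self) -> int:
        return self.value


def category_of(g: Glycan) -> SubsumptionCategory:
    """Assign the characterization category of a structure.

    Only inter-residue link positions on the parent side count as
    Saccharide-level "carbon bond" information; the child-side anomeric
    carbon is regarded as part of the link's connectivity convention.
    Substituent attachment positions never affect the category.
    """
    if any(m.anomer_determined for m in g.residues):
        return SubsumptionCategory.Saccharide
    if any(l.parent_positions is not UNDETERMINED for l in g.links):
        return SubsumptionCategory.Saccharide
    if g.links or any(m.ring_determined for m in g.residues):
        return SubsumptionCategory.Topology
    if any(m.stereo for m in g.residues):
        return SubsumptionCategory.Composition
    return SubsumptionCategory.BaseComposition


def _strip_anomer(m: Monosaccharide) -> Monosaccharide:
    if m.has_aldi:
        return m           # reduced end: determined open chain, kept
    return replace(m, anomer=UNDET)


def _strip_ring(m: Monosaccharide) -> Monosaccharide:
    if m.has_aldi:
        return m
    return replace(m, ring=UNDETERMINED)


def topology_of(g: Glycan) -> Glycan:
    """Remove anomeric configurations and parent-side link positions.

    Ring forms and connectivity (including the child-side anomeric carbon
    of each link and the link-atom types, which carry no positional
    information) are retained.  Idempotent and mass-preserving.
    """
    residues = tuple(_strip_anomer(m) for m in g.residues)
    links = tuple(replace(l, parent_positions=UNDETERMINED) for l in g.links)
    return Glycan(residues=residues, links=links, root=g.root,
                  floating_substituents=g.floating_substituents, name=g.name)


def composition_of(g: Glycan) -> Glycan:
    """Additionally remove ring forms and all inter-residue links.

    Substituents stay attached with their positions (the mass identity of
    residues such as HexNAc depends on them).  The result is a composition
    with an undetermined root (a lone residue keeps itself as root).
    """
    t = topology_of(g)
    residues = tuple(_strip_ring(m) for m in t.residues)
    root = 0 if len(residues) == 1 else UNDETERMINED
    return Glycan(residues=residues, links=(), root=root,
                  floating_substituents=g.floating_substituents, name=g.name)


def basecomposition_of(g: Glycan) -> Glycan:
    """Additionally remove all stereochemistry (stems become empty)."""
    c = composition_of(g)
    residues = tuple(replace(m, stereo=()) for m in c.residues)
    return Glycan(residues=residues, links=(), root=c.root,
                  floating_substituents=g.floating_substituents, name=g.name)


def archetype_of(g: Glycan) -> Glycan:
    """Remove only the reducing-end residue's anomeric and ring information.

    Applies to structures (and lone residues) with a reducing end; a
    multi-residue composition has no distinguished reducing end and raises
    :class:`NotApplicableError`.  A structure unchanged by this operation is
    itself an archetype.  An alditol-reduced reducing end is left unchanged:
    the reduction is determined chemistry, and removing it would change the
    mass.
    """
    if g.root is UNDETERMINED:
        raise NotApplicableError(
            "archetype is undefined for compositions (no reducing end)")
    root_m = g.residues[g.root]
    if root_m.has_aldi:
        return g
    new_root = replace(root_m, anomer=UNDET, ring=UNDETERMINED)
    residues = list(g.residues)
    residues[g.root] = new_root
    return Glycan(residues=tuple(residues), links=g.links, root=g.root,
                  floating_substituents=g.floating_substituents, name=g.name)
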