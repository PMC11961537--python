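"""Synthetic structure families with known ground-truth subsumption.

Fully defined seed structures ship with the package as GlycoCT documents;
families of partially characterized variants are derived from them by
chains of information-removing degradation operations, each of which emits
a ground-truth subsumption edge (the degraded structure subsumes its
input).  The families stand in for registry-scale data in every test:
each degradation removes exactly one kind of information, so all variants
of a seed share one molecular-weight class by construction — except for
reducing-end alditol reduction, which emits a non-mass-preserving edge.

Degradations never touch substituents.  Substituent attachment positions
are the one kind of removable information that carries no characterization
score, so leaving them alone keeps the score strictly monotone along every
generated mass-preserving edge.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace
from importlib import resources

from .glycoct import parse_glycoct, write_glycoct
from .model import (
    UNDETERMINED, UNDET, OPEN, Glycan, Link, Monosaccharide, canonical_form,
)
from .levels import archetype_of

__all__ = ["FIXTURE_NAMES", "SEED_NAMES", "fixture_text", "load_fixture",
           "seed_structures", "generate_family", "TrueEdge",
           "DEGRADATION_KINDS"]

#: All shipped GlycoCT fixture documents.
FIXTURE_NAMES = ("F1", "T1", "C1", "B1", "R1", "M1", "M2",
                 "GAL", "GLCNAC", "O1", "O2", "NG")

#: The fully defined seeds used to derive families.
SEED_NAMES = ("F1", "NG", "O1", "O2", "GAL", "GLCNAC")

DEGRADATION_KINDS = ("drop_anomer", "drop_ring", "drop_link_positions",
                     "drop_link", "drop_stereo", "reduce_root",
                     "to_archetype")


def fixture_text(name: str) -> str:
    """Verbatim GlycoCT text of a shipped fixture."""
    ref = resources.files("glysubsume") / "data" / f"{name}.glycoct"
    return ref.read_text()


def load_fixture(name: str) -> Glycan:
    """Parse a shipped fixture document."""
    return parse_glycoct(fixture_text(name), name=name)


def seed_structures():
    """The fully defined seed structures (all validate, all score 0)."""
    return [load_fixture(name) for name in SEED_NAMES]


@dataclass(frozen=True)
class TrueEdge:
    """Ground-truth edge: structure ``subsumer`` subsumes ``subsumed``
    (both are indices into the returned structure list)."""

    subsumer: int
    subsumed: int
    mass_preserving: bool = True


def _replace_residue(g: Glycan, idx: int, mono: Monosaccharide) -> Glycan:
    residues = list(g.residues)
    residues[idx] = mono
    return Glycan(residues=tuple(residues), links=g.links, root=g.root,
                  floating_substituents=g.floating_substituents)


def _applicable_ops(g: Glycan):
    """Enumerate every degradation applicable to ``g`` as (kind, target)."""
    ops = []
    for i, m in enumerate(g.residues):
        if m.anomer != UNDET and not m.has_aldi:
            ops.append(("drop_anomer", i))
        if m.ring is not UNDETERMINED and not m.has_aldi:
            ops.append(("drop_ring", i))
        if m.stereo:
            ops.append(("drop_stereo", i))
    for k, l in enumerate(g.links):
        if l.parent_positions is not UNDETERMINED:
            ops.append(("drop_link_positions", k))
    if g.links:
        ops.append(("drop_link", None))
    if g.root is not UNDETERMINED:
        root_m = g.residues[g.root]
        if root_m.anomer == UNDET and not root_m.has_aldi:
            ops.append(("reduce_root", None))
        if not root_m.has_aldi and (
                root_m.anomer != UNDET or root_m.ring is not UNDETERMINED):
            ops.append(("to_archetype", None))
    return ops


def apply_degradation(g: Glycan, kind: str, target):
    """Apply one degradation; returns (new_glycan, mass_preserving)."""
    if kind == "drop_anomer":
        return _replace_residue(g, target,
                                replace(g.residues[target], anomer=UNDET)), True
    if kind == "drop_ring":
        return _replace_residue(
            g, target, replace(g.residues[target], ring=UNDETERMINED)), True
    if kind == "drop_stereo":
        return _replace_residue(
            g, target, replace(g.residues[target], stereo=())), True
    if kind == "drop_link_positions":
        links = list(g.links)
        links[target] = replace(links[target], parent_positions=UNDETERMINED)
        return Glycan(residues=g.residues, links=tuple(links), root=g.root,
                      floating_substituents=g.floating_substituents), True
    if kind == "drop_link":
        root = 0 if len(g.residues) == 1 else UNDETERMINED
        return Glycan(residues=g.residues, links=(), root=root,
                      floating_substituents=g.floating_substituents), True
    if kind == "to_archetype":
        return archetype_of(g), True
    if kind == "reduce_root":
        root_m = g.residues[g.root]
        mono = replace(root_m, anomer=OPEN, ring=(0, 0),
                       modifications=root_m.modifications + ((1, "aldi"),))
        return _replace_residue(g, g.root, mono), False
    raise ValueError(f"unknown degradation kind {kind!r}")


def generate_family(seed: Glycan, n_variants: int, rng_seed: int):
    """Grow a family of degraded variants with known true edges.

    Starting from ``seed``, repeatedly picks a structure already in the
    family and one applicable degradation, records the resulting structure
    (deduplicated by canonical form) and the ground-truth edge
    *degraded subsumes input*.  Deterministic for a given ``rng_seed``;
    stops at ``n_variants`` structures or when the family saturates.

    Returns ``(structures, true_edges)`` with edges as :class:`TrueEdge`
    index pairs into ``structures`` (``structures[0]`` is the seed).
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    rng = random.Random(rng_seed)
    structures = [seed]
    index = {canonical_form(seed): 0}
    edges = set()
    attempts = 0
    max_attempts = 200 * n_variants
    while len(structures) < n_variants and attempts < max_attempts:
        attempts += 1
        src = rng.randrange(len(structures))
        g = structures[src]
        ops = _applicable_ops(g)
        if not ops:
            continue
        kind, target = ops[rng.randrange(len(ops))]
        if kind == "reduce_root" and rng.random() < 0.7:
            continue        # keep reduced structures a minority, as in practice
        new, mass_preserving = apply_degradation(g, kind, target)
        cf = canonical_form(new)
        if cf in index:
            dst = index[cf]
        else:
            dst = len(structures)
            structures.append(new)
            index[cf] = dst
        if dst != src:
            if mass_preserving:
                # removing information: the degraded structure subsumes
                edges.add(TrueEdge(subsumer=dst, subsumed=src))
            else:
                # alditol reduction: the unreduced input (undetermined
                # reducing-end anomer) subsumes the reduced structure
                edges.add(TrueEdge(subsumer=src, subsumed=dst,
                                   mass_preserving=False))
    return structures, sorted(edges, key=lambda e: (e.subsumer, e.subsumed))


def write_family(seed_name: str, n_variants: int, rng_seed: int, out_dir):
    """Write a family as GlycoCT files plus a ground-truth TSV.

    Files are named ``<seed>_<index>.glycoct``; ``truth.tsv`` lists
    subsumer/subsumed file stems and the mass-preserving flag.
    """
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = load_fixture(seed_name)
    structures, edges = generate_family(seed, n_variants, rng_seed)
    stems = []
    for i, g in enumerate(structures):
        stem = f"{seed_name}_{i:04d}"
        stems.append(stem)
        (out / f"{stem}.glycoct").write_text(write_glycoct(g))
    with open(out / "truth.tsv", "w") as fh:
        fh.write("subsumer\tsubsumed\tmass_preserving\n")
        for e in edges:
            fh.write(f"{stems[e.subsumer]}\t{stems[e.subsumed]}\t"
                     f"{str(e.mass_preserving).lower()}\n")
    return structures, edges
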