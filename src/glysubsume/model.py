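"""Core data model for partially characterized glycan structures.

A glycan is represented as a rooted directed graph of monosaccharides
connected by glycosidic links.  Every piece of structural information —
anomeric configuration, ring form, stereochemistry, linkage positions —
may independently be *undetermined*, which is what makes one description
subsume (be consistent with, but more general than) another.  Compositions
are glycans whose inter-residue links are entirely absent.

The module also provides structure-level utilities: a canonical form used
for equality and deduplication, validation, and the underivatized
monoisotopic mass used to group structures into molecular-weight classes.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

__all__ = [
    "UNDETERMINED",
    "ALPHA", "BETA", "OPEN", "UNDET",
    "SUPERCLASSES",
    "Monosaccharide", "Link", "Glycan", "MassValue",
    "GlycanError", "GlycanValidationError", "UnsupportedComponentError",
    "canonical_form", "underivatized_mass", "validate",
    "H2_MASS", "WATER_MASS",
]

#: Sentinel for any piece of structural information that is not determined.
#: ``None`` is used so that optional typing reads naturally; the alias exists
#: because "undetermined" is the domain concept, not mere absence.
UNDETERMINED = None

# Anomeric configuration codes (GlycoCT convention).
ALPHA, BETA, OPEN, UNDET = "a", "b", "o", "x"
_ANOMERS = {ALPHA, BETA, OPEN, UNDET}

#: Monosaccharide superclasses by carbon count.
SUPERCLASSES = {
    "TRI": 3, "TET": 4, "PEN": 5, "HEX": 6, "HEP": 7, "OCT": 8, "NON": 9,
}

#: Supported modification kinds (GlycoCT codes): deoxygenation, acid,
#: carbonyl (ketose), and alditol reduction of the reducing end.
MODIFICATIONS = {"d", "a", "keto", "aldi"}

#: Supported substituents and their elemental deltas relative to replacing
#: a hydroxyl hydrogen / hydroxyl group in the standard attachment.
SUBSTITUENT_FORMULAS = {
    "n-acetyl":   {"C": 2, "H": 3, "N": 1},
    "n-glycolyl": {"C": 2, "H": 3, "N": 1, "O": 1},
    "n":          {"H": 1, "N": 1, "O": -1},
    "sulfate":    {"S": 1, "O": 3},
    "phosphate":  {"P": 1, "O": 3, "H": 1},
}

# Monoisotopic atomic masses (Da).
_ATOMIC = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
}
WATER_MASS = 2 * _ATOMIC["H"] + _ATOMIC["O"]
H2_MASS = 2 * _ATOMIC["H"]


class GlycanError(Exception):
    """Base error for the glycan model."""


class GlycanValidationError(GlycanError):
    """Raised when an operation requires a valid glycan and gets violations."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("invalid glycan: " + "; ".join(self.violations))


class UnsupportedComponentError(GlycanError):
    """An unknown substituent or modification name was encountered."""


def _mod_sort_key(mod):
    pos, kind = mod
    return (-1 if pos is UNDETERMINED else pos, kind)


def _sub_sort_key(sub):
    name, pos, ltype = sub
    return (name, -1 if pos is UNDETERMINED else pos, ltype)


@dataclass(frozen=True)
class Monosaccharide:
    """One sugar residue with possibly-unknown characterization.

    Parameters
    ----------
    superclass : str
        Carbon-count class, one of ``TRI``..``NON``.
    stereo : tuple of str
        Configuration-stem codes in GlycoCT spelling (e.g. ``("dglc",)`` for
        D-glucose, ``("dgro", "dgal")`` for the sialic-acid backbone).  The
        empty tuple means *superclass only*: no stereochemistry information.
    anomer : str
        ``a`` (alpha), ``b`` (beta), ``o`` (open chain) or ``x``
        (undetermined).
    ring : (int, int) or UNDETERMINED
        Ring-closing carbon pair, e.g. ``(1, 5)`` for a pyranose; ``(0, 0)``
        for a determined open chain; UNDETERMINED when unknown.
    modifications : tuple of (pos, kind)
        Multiset of modifications; position is a 1-based carbon index or
        UNDETERMINED; kind in ``{"d", "a", "keto", "aldi"}``.  ``aldi`` marks
        an alditol-reduced residue and implies a determined open chain.
    substituents : tuple of (name, pos, linkage_type)
        Multiset of attached substituents; linkage_type is the two-letter
        parent+child GlycoCT linkage-atom code (e.g. ``"dn"`` for N-acetyl).
    """

    superclass: str
    stereo: tuple = ()
    anomer: str = UNDET
    ring: object = UNDETERMINED
    modifications: tuple = ()
    substituents: tuple = ()

    def __post_init__(self):
        if self.superclass not in SUPERCLASSES:
            raise GlycanError(f"unknown superclass {self.superclass!r}")
        if self.anomer not in _ANOMERS:
            raise GlycanError(f"unknown anomer code {self.anomer!r}")
        object.__setattr__(self, "stereo", tuple(self.stereo))
        object.__setattr__(
            self, "modifications",
            tuple(sorted((tuple(m) for m in self.modifications),
                         key=_mod_sort_key)))
        object.__setattr__(
            self, "substituents",
            tuple(sorted((tuple(s) for s in self.substituents),
                         key=_sub_sort_key)))

    @property
    def has_aldi(self) -> bool:
        return any(kind == "aldi" for _, kind in self.modifications)

    @property
    def anomer_determined(self) -> bool:
        """Whether the anomeric state carries information.

        An alditol residue has a chemically fixed open-chain reducing end
        and therefore counts as determined.
        """
        return self.anomer != UNDET or self.has_aldi

    @property
    def ring_determined(self) -> bool:
        return self.ring is not UNDETERMINED or self.has_aldi

    def descriptor(self) -> str:
        """Deterministic full text descriptor (used in canonical forms)."""
        ring = "x:x" if self.ring is UNDETERMINED else f"{self.ring[0]}:{self.ring[1]}"
        mods = ",".join(
            f"{'x' if p is UNDETERMINED else p}:{k}" for p, k in self.modifications)
        subs = ",".join(
            f"{n}@{'x' if p is UNDETERMINED else p}~{t}" for n, p, t in self.substituents)
        stem = "-".join(self.stereo) if self.stereo else "*"
        return f"{self.anomer}|{stem}|{self.superclass}|{ring}|{mods}|{subs}"

    def snfg_descriptor(self) -> str:
        """Residue identity at the level SNFG symbols resolve.

        Stereochemistry stems plus superclass plus modifications; anomeric
        configuration and ring form are not part of the symbol identity.
        """
        stem = "-".join(self.stereo)
        core = f"{stem}-{self.superclass}" if stem else self.superclass
        mods = "".join(
            f"|{'x' if p is UNDETERMINED else p}:{k}"
            for p, k in self.modifications if k != "aldi")
        return core + mods


@dataclass(frozen=True)
class Link:
    """A glycosidic link from a parent residue to a child residue.

    ``parents`` is a set of candidate parent residue indices: a singleton for
    a determined attachment, larger when only the set of possible attachment
    residues is known (partially determined topology).  ``parent_positions``
    is a set of candidate attachment carbons on the parent, or UNDETERMINED.
    """

    parents: frozenset
    child: int
    parent_positions: object = UNDETERMINED   # frozenset of int, or UNDETERMINED
    child_position: object = UNDETERMINED     # int or UNDETERMINED
    parent_type: str = "o"
    child_type: str = "d"

    def __post_init__(self):
        object.__setattr__(self, "parents", frozenset(self.parents))
        if self.parent_positions is not UNDETERMINED:
            object.__setattr__(self, "parent_positions",
                               frozenset(self.parent_positions))
        if not self.parents:
            raise GlycanError("link with no parent candidates")
        if self.child in self.parents:
            raise GlycanError("link parent equals child")

    @property
    def undetermined(self) -> bool:
        """True when the link leaves attachment information open (undetermined
        parent positions or an ambiguous candidate-parent set)."""
        return self.parent_positions is UNDETERMINED or len(self.parents) > 1


@dataclass
class Glycan:
    """A rooted directed graph of monosaccharides, or a composition.

    ``root`` is the reducing-end residue index; UNDETERMINED is permitted for
    multi-residue compositions only.  A single lone residue is its own
    reducing end.  ``floating_substituents`` are substituents present in the
    molecule but not attached to a particular residue.
    """

    residues: tuple
    links: tuple = ()
    root: object = UNDETERMINED
    floating_substituents: tuple = ()
    name: str = ""

    def __post_init__(self):
        self.residues = tuple(self.residues)
        self.links = tuple(self.links)
        self.floating_substituents = tuple(sorted(self.floating_substituents))
        if len(self.residues) == 1 and self.root is UNDETERMINED:
            self.root = 0

    @property
    def is_composition(self) -> bool:
        """True iff no inter-residue links are present."""
        return not self.links

    @property
    def n(self) -> int:
        return len(self.residues)

    def __eq__(self, other):
        if not isinstance(other, Glycan):
            return NotImplemented
        return canonical_form(self) == canonical_form(other)

    def __hash__(self):
        return hash(canonical_form(self))


@dataclass(frozen=True)
class MassValue:
    """Monoisotopic mass with its 2-decimal molecular-weight-class key."""

    monoisotopic_da: float

    @property
    def weight_class_key(self) -> float:
        return round(self.monoisotopic_da, 2)


# ---------------------------------------------------------------------------
# validation

def validate(g: Glycan) -> list:
    """Return the list of invariant violations (empty iff ``g`` is valid)."""
    out = []
    n = len(g.residues)
    if n == 0:
        return ["empty: glycan has no residues"]
    for l in g.links:
        bad = [i for i in set(l.parents) | {l.child} if not 0 <= i < n]
        if bad:
            out.append(f"index: link references missing residues {sorted(bad)}")
    if out:
        return out

    children = Counter(l.child for l in g.links)
    for idx, cnt in children.items():
        if cnt > 1:
            out.append(f"multiparent: residue {idx} is the child of {cnt} links")

    if g.links:
        if g.root is UNDETERMINED:
            out.append("root: structures with links must declare a root")
        elif g.root in children:
            out.append("root: the root residue has an incoming link")
        # connectivity over the union graph (any candidate parent connects)
        adj = defaultdict(set)
        for l in g.links:
            for p in l.parents:
                adj[p].add(l.child)
                adj[l.child].add(p)
        seen, stack = set(), [next(iter(adj))]
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            stack.extend(adj[v] - seen)
        if len(seen) != n:
            out.append("disconnected: link graph does not span all residues")
        # acyclicity of the directed union graph
        colour = {}

        def dfs(v):
            colour[v] = 1
            for l in g.links:
                if v in l.parents:
                    w = l.child
                    if colour.get(w) == 1:
                        return False
                    if colour.get(w, 0) == 0 and not dfs(w):
                        return False
            colour[v] = 2
            return True

        for v in range(n):
            if colour.get(v, 0) == 0 and not dfs(v):
                out.append("cycle: links form a directed cycle")
                break
    else:
        if n > 1 and g.root is not UNDETERMINED:
            # permitted but root must at least be a real residue
            if not 0 <= g.root < n:
                out.append("root: root index out of range")

    for ri, m in enumerate(g.residues):
        carbons = SUPERCLASSES[m.superclass]
        for pos, kind in m.modifications:
            if kind not in MODIFICATIONS:
                out.append(f"modification: unknown kind {kind!r} on residue {ri}")
            if pos is not UNDETERMINED and not 0 <= pos <= carbons:
                out.append(f"position: modification position {pos} out of range "
                           f"on residue {ri}")
        if m.has_aldi and m.anomer not in (OPEN, UNDET):
            out.append(f"aldi: residue {ri} is reduced but has a closed-ring "
                       f"anomeric configuration")
        for name, pos, _ in m.substituents:
            if pos is not UNDETERMINED and not 1 <= pos <= carbons:
                out.append(f"position: substituent position {pos} out of range "
                           f"on residue {ri}")
    for l in g.links:
        carbons = SUPERCLASSES[g.residues[l.child].superclass]
        if l.child_position is not UNDETERMINED and not 1 <= l.child_position <= carbons:
            out.append("position: link child position out of range")
        if l.parent_positions is not UNDETERMINED:
            for p in l.parents:
                pc = SUPERCLASSES[g.residues[p].superclass]
                for pos in l.parent_positions:
                    if not 1 <= pos <= pc:
                        out.append("position: link parent position out of range")
    return out


def _require_valid(g: Glycan):
    v = validate(g)
    if v:
        raise GlycanValidationError(v)


# ---------------------------------------------------------------------------
# mass

def elemental_formula(g: Glycan) -> Counter:
    """Elemental composition of the free, underivatized glycan.

    Built as the sum of free-monosaccharide formulas minus one water per
    residue beyond the first; link presence does not enter, so information
    removal (and in particular dropping links to form a composition) never
    changes the mass.
    """
    counts = Counter()
    for m in g.residues:
        c = SUPERCLASSES[m.superclass]
        counts.update({"C": c, "H": 2 * c, "O": c})
        for _, kind in m.modifications:
            if kind == "d":
                counts["O"] -= 1
            elif kind == "a":
                counts["O"] += 1
                counts["H"] -= 2
            elif kind == "keto":
                pass        # carbonyl relocation is formula-neutral
            elif kind == "aldi":
                counts["H"] += 2
            else:
                raise UnsupportedComponentError(f"modification {kind!r}")
        for name, _, _ in m.substituents:
            if name not in SUBSTITUENT_FORMULAS:
                raise UnsupportedComponentError(f"substituent {name!r}")
            counts.update(SUBSTITUENT_FORMULAS[name])
    for name in g.floating_substituents:
        if name not in SUBSTITUENT_FORMULAS:
            raise UnsupportedComponentError(f"substituent {name!r}")
        counts.update(SUBSTITUENT_FORMULAS[name])
    waters = len(g.residues) - 1
    counts["H"] -= 2 * waters
    counts["O"] -= waters
    return counts


def underivatized_mass(g: Glycan) -> MassValue:
    """Monoisotopic mass (Da) of the free, underivatized glycan.

    Monoisotopic (not average) mass is the grouping convention throughout
    this package, matching mass-spectrometry practice.
    """
    counts = elemental_formula(g)
    return MassValue(sum(_ATOMIC[el] * k for el, k in counts.items()))


# ---------------------------------------------------------------------------
# canonical form

_MAX_PERMUTATIONS = 100_000


def _link_invariant(l: Link):
    pp = (-1,) if l.parent_positions is UNDETERMINED else tuple(sorted(l.parent_positions))
    cp = -1 if l.child_position is UNDETERMINED else l.child_position
    return (len(l.parents), pp, cp, l.parent_type, l.child_type)


def _refine_colours(g: Glycan):
    """Colour-refinement partition of residues, isomorphism-invariant."""
    n = len(g.residues)
    base = [((0 if g.root == i else 1), g.residues[i].descriptor())
            for i in range(n)]
    order = sorted(set(base))
    colours = [order.index(b) for b in base]
    for _ in range(n):
        sigs = []
        for i in range(n):
            sig = []
            for l in g.links:
                li = _link_invariant(l)
                if i in l.parents:
                    sig.append(("P", li, colours[l.child]))
                if l.child == i:
                    sig.append(("C", li, tuple(sorted(colours[p] for p in l.parents))))
            sigs.append((colours[i], tuple(sorted(sig))))
        order = sorted(set(sigs))
        new = [order.index(s) for s in sigs]
        if new == colours:
            break
        colours = new
    return colours


def _serial_key(g: Glycan, order):
    pos = {ri: k for k, ri in enumerate(order)}
    res_part = tuple(g.residues[ri].descriptor() for ri in order)
    link_part = tuple(sorted(
        (tuple(sorted(pos[p] for p in l.parents)),
         pos[l.child],
         (-1,) if l.parent_positions is UNDETERMINED else tuple(sorted(l.parent_positions)),
         -1 if l.child_position is UNDETERMINED else l.child_position,
         l.parent_type, l.child_type)
        for l in g.links))
    root_part = -1 if g.root is UNDETERMINED else pos[g.root]
    return (res_part, link_part, g.floating_substituents, root_part)


def canonical_order(g: Glycan):
    """A canonical residue ordering: root first, then by refined colour,
    ties broken by minimizing the full serialization.

    Two isomorphic glycans receive identical serializations under their
    respective canonical orders.
    """
    colours = _refine_colours(g)
    groups = defaultdict(list)
    for i, c in enumerate(colours):
        groups[c].append(i)
    classes = [groups[c] for c in sorted(groups)]
    total = 1
    for cl in classes:
        total *= math.factorial(len(cl))
        if total > _MAX_PERMUTATIONS:
            raise GlycanError(
                "canonicalization: too many symmetric residue orderings")
    best = None
    for parts in itertools.product(*(itertools.permutations(cl) for cl in classes)):
        order = [i for part in parts for i in part]
        key = _serial_key(g, order)
        if best is None or key < best[0]:
            best = (key, order)
    return best[1]


def canonical_form(g: Glycan) -> str:
    """Deterministic string equal for exactly the isomorphic glycans.

    Cached on the glycan; glycans are treated as immutable once built.
    """
    cached = getattr(g, "_canonical_cache", None)
    if cached is not None:
        return cached
    _require_valid(g)
    key = _serial_key(g, canonical_order(g))
    res_part, link_part, floats, root = key
    lines = ["RES[" + ";".join(res_part) + "]"]
    if link_part:
        lines.append("LIN[" + ";".join(
            f"{'|'.join(map(str, ps))}{pt}({'|'.join(map(str, pp))}+{cp}){c}{ct}"
            for ps, c, pp, cp, pt, ct in link_part) + "]")
    if floats:
        lines.append("FLOAT[" + ",".join(floats) + "]")
    lines.append(f"ROOT={root}")
    result = "\n".join(lines)
    g._canonical_cache = result
    return result
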