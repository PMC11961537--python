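"""Composition-string synonyms and SNFG-consistency checking.

Compositions built from the supported residue vocabulary — Hex, HexNAc,
Fuc, dHex, NeuAc, NeuGc, KDN, HexA, Pent — receive composition strings in
Byonic (``HexNAc(4)Hex(5)NeuAc(2)``), single-letter (``N4H5S2``) and
UniCarbKB-style (``HexNAc4Hex5NeuAc2``) formats.  The single-letter and
UniCarbKB dialects here are this package's documented convention (the
letter map can be remapped via :data:`SINGLE_LETTER`).

SNFG consistency flags glycans that consist entirely of monosaccharides
and substituents from a user-supplied whitelist of SNFG-style residue
descriptors; a default whitelist covering the composition vocabulary plus
sulfate and phosphate ships with the package.
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass
from importlib import resources

from .model import Glycan, GlycanError, Monosaccharide

__all__ = ["CompositionName", "SNFGWhitelist", "composition_name",
           "composition_counts", "parse_byonic", "snfg_consistent",
           "load_whitelist", "default_whitelist",
           "COMPOSITION_ORDER", "SINGLE_LETTER"]

#: Fixed output ordering of composition residue names.
COMPOSITION_ORDER = ("HexNAc", "Hex", "Fuc", "dHex", "NeuAc", "NeuGc",
                     "KDN", "HexA", "Pent")

#: Single-letter codes for the supported residue names.
SINGLE_LETTER = {"HexNAc": "N", "Hex": "H", "Fuc": "F", "dHex": "D",
                 "NeuAc": "S", "NeuGc": "G", "KDN": "K", "HexA": "A",
                 "Pent": "P"}


def _mod_kinds(m: Monosaccharide):
    return tuple(sorted(kind for _, kind in m.modifications))


def _sub_names(m: Monosaccharide):
    return tuple(sorted(name for name, _, _ in m.substituents))


def _residue_name(m: Monosaccharide):
    """Map one residue to a supported composition name, or None.

    Matching is by superclass, modification kinds and substituents; ring
    and anomeric state are irrelevant at composition level.  A deoxyhexose
    maps to Fuc only when its stereochemistry is present (galacto
    configuration); with stereochemistry removed it is just dHex.
    """
    kinds = _mod_kinds(m)
    subs = _sub_names(m)
    if m.superclass == "HEX":
        if kinds == ():
            if subs == ():
                return "Hex"
            if subs == ("n-acetyl",):
                return "HexNAc"
            return None
        if kinds == ("d",) and subs == ():
            if m.stereo and m.stereo[-1].endswith("gal"):
                return "Fuc"
            if not m.stereo:
                return "dHex"
            return None
        if kinds == ("a",) and subs == ():
            return "HexA"
        return None
    if m.superclass == "PEN" and kinds == () and subs == ():
        return "Pent"
    if m.superclass == "NON" and kinds == ("a", "d", "keto"):
        if subs == ("n-acetyl",):
            return "NeuAc"
        if subs == ("n-glycolyl",):
            return "NeuGc"
        if subs == ():
            return "KDN"
        return None
    return None


def composition_counts(g: Glycan):
    """Counts of supported residue names for a composition, or None.

    None signals an unsupported input: a structure with links, a residue
    outside the supported vocabulary, or floating substituents (which have
    no place in a composition string).
    """
    if not g.is_composition or g.floating_substituents:
        return None
    counts = Counter()
    for m in g.residues:
        name = _residue_name(m)
        if name is None:
            return None
        counts[name] += 1
    return dict(counts)


@dataclass(frozen=True)
class CompositionName:
    counts: dict
    byonic: str
    single_letter: str
    unicarbkb: str


def _render(counts):
    ordered = [(name, counts[name]) for name in COMPOSITION_ORDER
               if counts.get(name)]
    byonic = "".join(f"{name}({k})" for name, k in ordered)
    single = "".join(f"{SINGLE_LETTER[name]}{k}" for name, k in ordered)
    unicarb = "".join(f"{name}{k}" for name, k in ordered)
    return CompositionName(counts=dict(counts), byonic=byonic,
                           single_letter=single, unicarbkb=unicarb)


def composition_name(g: Glycan, format: str = "byonic"):
    """Composition string of ``g`` in the requested format, or None."""
    counts = composition_counts(g)
    if not counts:
        return None
    name = _render(counts)
    try:
        return getattr(name, format)
    except AttributeError:
        raise GlycanError(f"unknown composition format {format!r}")


_BYONIC_RE = re.compile(r"([A-Za-z]+)\((\d+)\)")


def parse_byonic(text: str):
    """Parse a Byonic composition string back into name counts.

    Provided for mzIdentML-style composition lookup; inverse of the
    ``byonic`` rendering.
    """
    counts = {}
    consumed = 0
    for m in _BYONIC_RE.finditer(text):
        if m.start() != consumed:
            raise GlycanError(f"malformed Byonic string {text!r}")
        consumed = m.end()
        name, k = m.group(1), int(m.group(2))
        if name not in COMPOSITION_ORDER:
            raise GlycanError(f"unsupported residue name {name!r}")
        counts[name] = counts.get(name, 0) + k
    if consumed != len(text) or not counts:
        raise GlycanError(f"malformed Byonic string {text!r}")
    return counts


# ---------------------------------------------------------------------------
# SNFG whitelist

@dataclass(frozen=True)
class SNFGWhitelist:
    """Monosaccharide descriptors and substituent names considered SNFG."""

    residues: frozenset
    substituents: frozenset
    source_file: str = ""


def load_whitelist(path) -> SNFGWhitelist:
    """Load a whitelist TSV with columns ``name`` and ``glycoct_descriptor``.

    Substituent rows carry a descriptor of the form ``s:<name>``.
    """
    residues, substituents = set(), set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or \
                "glycoct_descriptor" not in reader.fieldnames:
            raise GlycanError(
                f"whitelist {path} lacks a glycoct_descriptor column")
        for row in reader:
            desc = row["glycoct_descriptor"].strip()
            if desc.startswith("s:"):
                substituents.add(desc[2:])
            elif desc:
                residues.add(desc)
    if not residues:
        raise GlycanError(f"whitelist {path} is empty")
    return SNFGWhitelist(residues=frozenset(residues),
                         substituents=frozenset(substituents),
                         source_file=str(path))


def default_whitelist() -> SNFGWhitelist:
    """The whitelist shipped with the package."""
    ref = resources.files("glysubsume") / "data" / "snfg_whitelist.tsv"
    with resources.as_file(ref) as path:
        return load_whitelist(path)


def snfg_consistent(g: Glycan, wl: SNFGWhitelist) -> bool:
    """True iff every residue descriptor and every substituent (attached or
    floating) of ``g`` is in the whitelist."""
    for m in g.residues:
        if m.snfg_descriptor() not in wl.residues:
            return False
        for name, _, _ in m.substituents:
            if name not in wl.substituents:
                return False
    for name in g.floating_substituents:
        if name not in wl.substituents:
            return False
    return True
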