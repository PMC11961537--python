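"""Reading and writing a documented GlycoCT-condensed dialect.

The dialect covers RES/LIN documents with basetype (``b:``) and substituent
(``s:``) residues.  Compositions are documents whose only LIN entries attach
substituents (GlyTouCan's UND-block encoding is deliberately not supported
and is rejected with an explicit error, as are repeating units).  Partially
determined topology is expressed by a LIN entry whose parent residue index
is a candidate list, e.g. ``1|2o(-1+1)4d``.

Undetermined markers follow GlycoCT: ``x`` anomer, ``x:x`` ring, ``-1``
positions, and basetypes without configuration stems (``b:x-HEX-x:x``) for
superclass-only residues.
"""

from __future__ import annotations

import re
from collections import defaultdict

from .model import (
    UNDETERMINED, Glycan, GlycanError, Link, Monosaccharide,
    canonical_order, validate, GlycanValidationError,
)

__all__ = ["parse_glycoct", "write_glycoct", "ParseError",
           "UnsupportedFeatureError"]


class ParseError(GlycanError):
    """Grammar violation, with the offending 1-based line number."""

    def __init__(self, message, lineno=None):
        self.lineno = lineno
        where = f" (line {lineno})" if lineno is not None else ""
        super().__init__(f"{message}{where}")


class UnsupportedFeatureError(ParseError):
    """Document uses a GlycoCT feature outside the dialect (REP/UND/ALT)."""


_RES_RE = re.compile(r"^(\d+)([bs]):(.*)$")
_LIN_RE = re.compile(
    r"^(\d+):(\d+(?:\|\d+)*)([odnh])"
    r"\((-1|\d+(?:\|\d+)*)\+(-1|\d+)\)"
    r"(\d+)([odnh])$")
_RING_RE = re.compile(r"^(x|\d+):(x|\d+)$")


def _parse_basetype(body, lineno):
    """Parse e.g. ``b-dglc-HEX-1:5|6:d`` into Monosaccharide pieces."""
    parts = body.split("|")
    core = parts[0].split("-")
    if len(core) < 3:
        raise ParseError(f"malformed basetype {body!r}", lineno)
    anomer = core[0]
    ring_m = _RING_RE.match(core[-1])
    if not ring_m:
        raise ParseError(f"malformed ring {core[-1]!r}", lineno)
    if ring_m.group(1) == "x" or ring_m.group(2) == "x":
        ring = UNDETERMINED
    else:
        ring = (int(ring_m.group(1)), int(ring_m.group(2)))
    superclass = core[-2]
    stems = tuple(core[1:-2])
    if stems == ("x",):        # explicit unknown-configuration marker
        stems = ()
    mods = []
    for modpart in parts[1:]:
        try:
            pos_s, kind = modpart.split(":")
        except ValueError:
            raise ParseError(f"malformed modification {modpart!r}", lineno)
        pos = UNDETERMINED if pos_s in ("x", "-1") else int(pos_s)
        mods.append((pos, kind))
    try:
        return Monosaccharide(superclass=superclass, stereo=stems,
                              anomer=anomer, ring=ring,
                              modifications=tuple(mods))
    except GlycanError as e:
        raise ParseError(str(e), lineno)


def parse_glycoct(text: str, name: str = "") -> Glycan:
    """Parse a GlycoCT-condensed document into a :class:`Glycan`.

    RES-only documents (apart from substituent attachments) become
    compositions.  Raises :class:`UnsupportedFeatureError` on REP/UND/ALT
    sections and :class:`ParseError` on grammar violations.
    """
    lines = [(i + 1, ln.strip()) for i, ln in enumerate(text.splitlines())]
    lines = [(no, ln) for no, ln in lines if ln]
    for no, ln in lines:
        if re.match(r"^(REP|UND|ALT)\d*$", ln):
            raise UnsupportedFeatureError(
                f"GlycoCT section {ln!r} is not supported "
                "(repeating units / underdetermined blocks)", no)
    if not lines or lines[0][1] != "RES":
        raise ParseError("document must start with a RES section",
                         lines[0][0] if lines else None)

    res_entries = {}      # doc index -> ("b", Monosaccharide) | ("s", name)
    lin_lines = []
    section = "RES"
    for no, ln in lines[1:]:
        if ln == "LIN":
            section = "LIN"
            continue
        if section == "RES":
            m = _RES_RE.match(ln)
            if not m:
                raise ParseError(f"malformed RES entry {ln!r}", no)
            idx, kind, body = int(m.group(1)), m.group(2), m.group(3)
            if idx in res_entries:
                raise ParseError(f"duplicate residue index {idx}", no)
            if kind == "b":
                res_entries[idx] = ("b", _parse_basetype(body, no))
            else:
                res_entries[idx] = ("s", body)
        else:
            m = _LIN_RE.match(ln)
            if not m:
                raise ParseError(f"malformed LIN entry {ln!r}", no)
            lin_lines.append((no, m))

    b_indices = sorted(i for i, (k, _) in res_entries.items() if k == "b")
    if not b_indices:
        raise ParseError("document declares no monosaccharides")
    remap = {doc: new for new, doc in enumerate(b_indices)}

    sub_attach = defaultdict(list)   # b residue -> substituent tuples
    links = []
    used_subs = set()
    for no, m in lin_lines:
        parents = [int(p) for p in m.group(2).split("|")]
        ptype, ctype = m.group(3), m.group(7)
        ppos_s, cpos_s = m.group(4), m.group(5)
        child = int(m.group(6))
        for p in parents + [child]:
            if p not in res_entries:
                raise ParseError(f"LIN references missing residue {p}", no)
        ppos = (UNDETERMINED if ppos_s == "-1"
                else frozenset(int(x) for x in ppos_s.split("|")))
        cpos = UNDETERMINED if cpos_s == "-1" else int(cpos_s)
        ckind = res_entries[child][0]
        if ckind == "s":
            if len(parents) != 1:
                raise ParseError(
                    "candidate parents are not supported for substituent "
                    "attachments", no)
            pkind = res_entries[parents[0]][0]
            if pkind != "b":
                raise ParseError("substituent attached to a substituent", no)
            if child in used_subs:
                raise ParseError(f"substituent {child} attached twice", no)
            used_subs.add(child)
            pos = UNDETERMINED if ppos is UNDETERMINED else min(ppos)
            sub_attach[remap[parents[0]]].append(
                (res_entries[child][1], pos, ptype + ctype))
        else:
            for p in parents:
                if res_entries[p][0] != "b":
                    raise ParseError("monosaccharide linked under a "
                                     "substituent", no)
            links.append(Link(parents=frozenset(remap[p] for p in parents),
                              child=remap[child],
                              parent_positions=ppos, child_position=cpos,
                              parent_type=ptype, child_type=ctype))

    floating = tuple(sorted(
        res_entries[i][1] for i, (k, _) in res_entries.items()
        if k == "s" and i not in used_subs))

    final_res = []
    for doc in b_indices:
        mono = res_entries[doc][1]
        subs = sub_attach.get(remap[doc], [])
        if subs:
            mono = Monosaccharide(
                superclass=mono.superclass, stereo=mono.stereo,
                anomer=mono.anomer, ring=mono.ring,
                modifications=mono.modifications,
                substituents=tuple(subs))
        final_res.append(mono)

    root = UNDETERMINED
    if links:
        children = {l.child for l in links}
        roots = [i for i in range(len(final_res)) if i not in children]
        if len(roots) == 1:
            root = roots[0]
        # otherwise leave undetermined; validate() reports disconnection
    g = Glycan(residues=tuple(final_res), links=tuple(links), root=root,
               floating_substituents=floating, name=name)
    return g


# ---------------------------------------------------------------------------
# writing

def _format_basetype(m: Monosaccharide) -> str:
    ring = "x:x" if m.ring is UNDETERMINED else f"{m.ring[0]}:{m.ring[1]}"
    if m.stereo:
        body = f"{m.anomer}-{'-'.join(m.stereo)}-{m.superclass}-{ring}"
    else:
        body = f"{m.anomer}-{m.superclass}-{ring}"
    for pos, kind in m.modifications:
        body += f"|{'-1' if pos is UNDETERMINED else pos}:{kind}"
    return body


def write_glycoct(g: Glycan) -> str:
    """Serialize ``g`` in canonical residue order (root first).

    ``parse_glycoct(write_glycoct(g))`` is isomorphic to ``g``.
    """
    violations = validate(g)
    if violations:
        raise GlycanValidationError(violations)
    order = canonical_order(g)
    res_lines = []
    sub_links = []           # (parent_doc_idx, pos, ltype, sub_doc_idx)
    doc_idx = {}
    num = 0
    for ri in order:
        mono = g.residues[ri]
        num += 1
        doc_idx[ri] = num
        res_lines.append(f"{num}b:{_format_basetype(mono)}")
        for name, pos, ltype in mono.substituents:
            num += 1
            res_lines.append(f"{num}s:{name}")
            sub_links.append((doc_idx[ri], pos, ltype, num))
    for name in g.floating_substituents:
        num += 1
        res_lines.append(f"{num}s:{name}")

    lin_entries = []
    for pnum, pos, ltype, snum in sub_links:
        ppos = "-1" if pos is UNDETERMINED else str(pos)
        lin_entries.append((pnum, 0, snum,
                            f"{pnum}{ltype[0]}({ppos}+1){snum}{ltype[1]}"))
    for l in g.links:
        pnums = sorted(doc_idx[p] for p in l.parents)
        ppos = ("-1" if l.parent_positions is UNDETERMINED
                else "|".join(str(p) for p in sorted(l.parent_positions)))
        cpos = "-1" if l.child_position is UNDETERMINED else str(l.child_position)
        lin_entries.append((pnums[0], 1, doc_idx[l.child],
                            f"{'|'.join(map(str, pnums))}{l.parent_type}"
                            f"({ppos}+{cpos}){doc_idx[l.child]}{l.child_type}"))
    lin_entries.sort()

    out = ["RES"] + res_lines
    if lin_entries:
        out.append("LIN")
        out.extend(f"{i + 1}:{body}" for i, (_, _, _, body) in enumerate(lin_entries))
    return "\n".join(out) + "\n"
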