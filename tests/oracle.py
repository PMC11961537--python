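"""Independent brute-force oracles for the test suite.

Everything here enumerates exhaustively (all residue bijections, all link
assignments, all substituent pairings) and is deliberately written without
reference to the engine's search machinery, so agreement between the two
routes is meaningful.  Only usable at small residue counts.
"""

import itertools
from collections import Counter

from glysubsume.model import UNDETERMINED


def _sub_pairings(ma, mb):
    """Yield the leftover name-multiset of every valid injective pairing of
    ma's substituents into mb's (names/linkage types equal; an undetermined
    subsumer position matches any position)."""
    asubs, bsubs = ma.substituents, mb.substituents
    if len(asubs) > len(bsubs):
        return
    for chosen in itertools.permutations(range(len(bsubs)), len(asubs)):
        ok = True
        for (an, ap, at), bi in zip(asubs, chosen):
            bn, bp, bt = bsubs[bi]
            if an != bn or at != bt:
                ok = False
                break
            if ap is not UNDETERMINED and ap != bp:
                ok = False
                break
        if ok:
            leftover = Counter(bsubs[i][0] for i in range(len(bsubs))
                               if i not in chosen)
            yield leftover


def _mono_ok(ma, mb, skip_reducing_end=False):
    """All leftover options for residue pair (ma subsumes mb), or []."""
    if ma.superclass != mb.superclass:
        return []
    if ma.stereo and tuple(ma.stereo) != tuple(mb.stereo):
        return []
    if skip_reducing_end:
        if tuple(m for m in ma.modifications if m[1] != "aldi") != \
                tuple(m for m in mb.modifications if m[1] != "aldi"):
            return []
    else:
        if tuple(ma.modifications) != tuple(mb.modifications):
            return []
        if ma.ring is not UNDETERMINED and ma.ring != mb.ring:
            return []
        if ma.anomer != "x" and ma.anomer != mb.anomer:
            return []
    return list(_sub_pairings(ma, mb))


def _link_ok(la, lb, mapping):
    if mapping[la.child] != lb.child:
        return False
    if not set(lb.parents) <= {mapping[p] for p in la.parents}:
        return False
    if la.parent_positions is not UNDETERMINED:
        if lb.parent_positions is UNDETERMINED:
            return False
        if not set(lb.parent_positions) <= set(la.parent_positions):
            return False
    if la.child_position is not UNDETERMINED and \
            la.child_position != lb.child_position:
        return False
    return la.parent_type == lb.parent_type and \
        la.child_type == lb.child_type


def oracle_subsumes(a, b, reduced_pair=False):
    """Exhaustive re-derivation of the subsumption decision."""
    n = len(a.residues)
    if n != len(b.residues):
        return False
    if b.is_composition and not a.is_composition:
        return False

    excluded_b = None
    if reduced_pair:
        aldi = [i for i, m in enumerate(b.residues) if m.has_aldi]
        if len(aldi) != 1:
            return False
        excluded_b = aldi[0]

    for perm in itertools.permutations(range(n)):
        mapping = {i: perm[i] for i in range(n)}
        if not a.is_composition and not b.is_composition:
            if mapping[a.root] != b.root:
                continue
        if reduced_pair:
            a_end = [i for i in range(n) if mapping[i] == excluded_b][0]
            am = a.residues[a_end]
            if am.anomer != "x" or am.has_aldi:
                continue
        options_per_pair = []
        feasible = True
        for i in range(n):
            skip = reduced_pair and mapping[i] == excluded_b
            opts = _mono_ok(a.residues[i], b.residues[mapping[i]],
                            skip_reducing_end=skip)
            if not opts:
                feasible = False
                break
            options_per_pair.append(opts)
        if not feasible:
            continue
        for combo in itertools.product(*options_per_pair):
            pool = Counter()
            for leftover in combo:
                pool.update(leftover)
            pool.update(b.floating_substituents)
            if pool != Counter(a.floating_substituents):
                continue
            if a.is_composition:
                return True
            # all b links matched to distinct a links
            alinks, blinks = list(a.links), list(b.links)
            if len(blinks) > len(alinks):
                continue
            found = False
            for assign in itertools.permutations(range(len(alinks)),
                                                 len(blinks)):
                if all(_link_ok(alinks[ai], blinks[bi], mapping)
                       for bi, ai in enumerate(assign)):
                    unused = set(range(len(alinks))) - set(assign)
                    if all(alinks[ai].parent_positions is UNDETERMINED
                           or len(alinks[ai].parents) > 1 for ai in unused):
                        found = True
                        break
            if found:
                return True
    return False


def oracle_closure(pairs):
    """Transitive closure of an edge set by iterated squaring."""
    closure = set(pairs)
    while True:
        extra = {(u, w) for (u, v) in closure for (v2, w) in closure
                 if v == v2} - closure
        if not extra:
            return closure
        closure |= extra
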