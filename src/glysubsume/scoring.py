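"""The 0-10,000 (lack of) characterization score.

The score summarizes how much structural information a glycan description
is missing.  Fully determined structures score 0; multi-residue base
compositions score 10,000.  Each of the ``n`` monosaccharides is scored for
its missing residue-level information and the scores averaged; the ``n-1``
conceptual links between non-reducing-end residues and their parents are
scored next — a conceptual link exists, and is maximally penalized, even
when no link is present at all (compositions) — and averaged.  The final
score is the weighted sum ``0.4 * mono_avg + 0.6 * link_avg``.  For a lone
residue there are no conceptual links; the link term contributes 0 and the
weights are deliberately not renormalized, which pins the single-residue
base-composition score at 0.4 * 10,000 = 4,000 and the single-residue
composition score at 2,000.

Component penalties:

====================================  ======
missing information                   penalty
====================================  ======
residue: stereochemistry               5000
residue: ring form                     2500
residue: anomeric configuration        2500
link: absent (conceptual only)        10000
link: ambiguous parent residue         6000
link: undetermined attachment carbon   2000
====================================  ======

An alditol-reduced residue has a chemically determined open-chain reducing
end: its ring and anomeric components score 0.  Information removal never
decreases any component, so the score is strictly monotone along
mass-preserving subsumption edges (substituent attachment positions carry
no score and are the one unscored degree of freedom).
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import (
    UNDETERMINED, UNDET, Glycan, Link, Monosaccharide,
)

__all__ = ["ScoreComponents", "mono_score", "link_score",
           "characterization_score", "score_components",
           "MONO_WEIGHT", "LINK_WEIGHT", "ABSENT"]

MONO_WEIGHT = 0.4
LINK_WEIGHT = 0.6

#: Sentinel passed to :func:`link_score` for the conceptual link of a
#: composition, where no link object exists at all.
ABSENT = "ABSENT"

_STEREO_PENALTY = 5000.0
_RING_PENALTY = 2500.0
_ANOMER_PENALTY = 2500.0
_LINK_ABSENT = 10000.0
_LINK_AMBIGUOUS_PARENT = 6000.0
_LINK_UNDET_POSITION = 2000.0


def mono_score(m: Monosaccharide) -> float:
    """Penalty in [0, 10000] for missing residue-level information."""
    penalty = 0.0
    if not m.stereo:
        penalty += _STEREO_PENALTY
    if not m.ring_determined:
        penalty += _RING_PENALTY
    if not m.anomer_determined:
        penalty += _ANOMER_PENALTY
    return penalty


def link_score(l) -> float:
    """Penalty in [0, 10000] for a conceptual link.

    ``ABSENT`` stands for the conceptual link of a composition.  An
    ambiguous candidate-parent set dominates an undetermined attachment
    carbon: not knowing *which* residue the child hangs from is less
    characterized than not knowing the carbon.
    """
    if l is ABSENT:
        return _LINK_ABSENT
    if len(l.parents) > 1:
        return _LINK_AMBIGUOUS_PARENT
    if l.parent_positions is UNDETERMINED or l.child_position is UNDETERMINED:
        return _LINK_UNDET_POSITION
    return 0.0


@dataclass(frozen=True)
class ScoreComponents:
    mono_penalties: tuple
    link_penalties: tuple
    mono_avg: float
    link_avg: float
    final: float


def score_components(g: Glycan) -> ScoreComponents:
    """Full score breakdown for ``g``."""
    monos = tuple(mono_score(m) for m in g.residues)
    mono_avg = sum(monos) / len(monos)
    n = len(g.residues)
    if n == 1:
        links = ()
        link_avg = 0.0
    elif g.is_composition:
        links = (ABSENT,) * (n - 1)
        link_avg = _LINK_ABSENT
    else:
        links = tuple(link_score(l) for l in g.links)
        link_avg = sum(links) / len(links)
    final = MONO_WEIGHT * mono_avg + LINK_WEIGHT * link_avg
    link_pen = tuple(_LINK_ABSENT if l is ABSENT else l for l in links)
    return ScoreComponents(mono_penalties=monos, link_penalties=link_pen,
                           mono_avg=mono_avg, link_avg=link_avg, final=final)


def characterization_score(g: Glycan) -> float:
    """The (lack of) characterization score of ``g``, in [0, 10000]."""
    return score_components(g).final
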