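# Methods

This note records the models, conventions and numerical choices behind
`glysubsume`, including the points where the design was genuinely open and
what the package chose.

## Glycan representation

A glycan is a set of monosaccharide residues plus a set of directed links,
rooted at the reducing end.  Every feature can independently be
undetermined:

| feature | determined form | undetermined form |
|---|---|---|
| anomeric configuration | `a`, `b`, or `o` (open) | `x` |
| ring form | carbon pair, e.g. `(1,5)`; `(0,0)` = open chain | unknown |
| stereochemistry | GlycoCT stems, e.g. `dglc` | empty (superclass only) |
| link parent position | set of carbons | unknown |
| link parent residue | singleton set | candidate set (`1\|2o(...)`) |

Modifications are restricted to `{deoxy, acid, keto, aldi}` and
substituents to `{n-acetyl, n-glycolyl, n, sulfate, phosphate}` — enough to
express Hex, HexNAc, dHex/Fuc, NeuAc, NeuGc, KDN, HexA and Pent, the
vocabulary the composition strings support.  Repeating units, cyclic
glycans and the full GlycoCT modification table are out of scope and are
rejected explicitly rather than silently.

A *composition* is a glycan with no inter-residue links; its root is
undetermined unless it has a single residue, in which case that residue is
its own reducing end (this is what lets lone monosaccharides have
archetypes, which they demonstrably do in practice).

**Canonical form.** Equality and deduplication use a canonical
serialization: colour refinement partitions residues by an
isomorphism-invariant signature (root flag, full residue descriptor,
iterated neighbourhood signatures), then the serialization is minimized
over the residual within-class permutations.  The permutation product is
bounded (10^5); symmetric structures such as a topology-level biantennary
N-glycan stay at ~2^4 candidate orders after refinement.

**Mass.** Underivatized monoisotopic mass, computed as the sum of free
monosaccharide formulas (CnH2nOn by superclass, adjusted per modification
and substituent) minus one water per residue beyond the first.  Using the
residue count rather than the link count makes every information-removal
operation mass-preserving by construction.  Monoisotopic rather than
average mass is the deliberate convention: any consistent choice yields the
same grouping, and monoisotopic matches mass-spectrometry practice.  Weight
classes are keyed on the mass rounded to 2 decimals.  `aldi` adds H2
(2.02 Da at 2 decimals).

## Subsumption decision

`subsumes(a, b)` enumerates perfect matchings of residues (backtracking,
most-constrained residue first) such that each residue of `a` subsumes its
partner: equal superclass; stereochemistry empty or equal; ring unknown or
equal; anomer undetermined or equal; modification multisets equal;
substituents matched by (name, linkage-type) with undetermined positions
allowed on the subsumer side only.  Residue-attached substituents of `b`
left unmatched are permissible only when claimed by floating substituents
of `a`; the global balance `floating(a) = leftovers + floating(b)` must
hold, which is exactly the mass-preservation constraint.

Link matching: every link of `b` must be subsumed by a distinct link of
`a` (mapped endpoints consistent, subsumer position sets undetermined or
supersets, linkage-atom types equal); unmatched links of `a` are permitted
only when undetermined (unknown parent positions or an ambiguous
candidate-parent set) — the deliberate reading of "some undetermined links
of the subsumer may remain unmatched".  When `a` is a composition the link
check is skipped entirely; when `b` is a composition and `a` is not, the
answer is no.  Roots must map to roots when both structures have one.

**Alditol-reduced reducing ends.** A reduced structure has a different
mass, so it is *redundantly* added to the weight group of its unreduced
counterpart (mass − H2) and compared there under a special rule: the
reducing-end residue pair is excluded from anomeric/ring/aldi comparison,
and the unreduced side's reducing-end anomer must be undetermined — a
β-specified structure is differently (not less) characterized than its
alditol.  These comparisons yield edges flagged non-mass-preserving; a
reduced structure never subsumes an unreduced one.

**DAG construction.** Isomorphic duplicates collapse to one node
(accessions become synonyms; without accessions, ids `SYNnnnn` are assigned
in canonical-form order, making the build order-independent).  All pairwise
edges within each weight group are computed, then the combined edge set is
transitively reduced (networkx); a cycle among distinct canonical forms
would be an antisymmetry violation and raises.  Cross-weight-group pairs
other than the alditol rule are never compared.

Complexity: the matcher is exponential in the worst case (it is a labelled
graph-isomorphism-style search); the cheap prechecks (superclass and
substituent multisets) and most-constrained-first ordering keep the
fixture-scale workloads (≤ 12 residues, ≤ 50-structure groups) well under
a second.  Oracle-backed tests compare it against exhaustive bijection
enumeration on families of ≤ 3-residue seeds.

## Levels and archetypes

Category assignment keys on information presence: any determined anomer or
any determined *parent-side* link position → Saccharide; else any link or
determined ring → Topology; else any stereochemistry → Composition; else
BaseComposition.  MolecularWeight is reserved for weight-class ontology
terms.  Two conventions worth noting:

* The child-side link position (the anomeric carbon of the child) is
  treated as part of the link's connectivity convention, not as
  Saccharide-level information, and is retained by `topology_of`.  This
  matches the standard topology encoding `1o(-1+1)3d`.
* `aldi` counts as a determined anomeric/ring state everywhere: a reduced
  reducing end is *more* characterized, not less.  Consequently level
  operations never strip `aldi` (they are all mass-preserving), a reduced
  structure is its own archetype, and reduced structures remain Saccharide
  under `topology_of`.

`topology_of` removes anomers and parent-side link positions;
`composition_of` additionally removes rings and all inter-residue links
(substituent attachments, including their positions, are retained — the
mass identity of HexNAc depends on them); `basecomposition_of` additionally
empties the stereochemistry.  All are idempotent.  `archetype_of` removes
only the root's anomer and ring; it applies to rooted structures and lone
residues, and raises for multi-residue compositions, which have no
distinguished reducing end.  Link-atom types survive `topology_of` (they
carry no positional information).

## Characterization score

`score = 0.4 · mean(residue penalties) + 0.6 · mean(conceptual-link
penalties)`, with residue penalties 5000 (no stereochemistry) + 2500 (no
ring) + 2500 (no anomer), and conceptual-link penalties 10000 (absent —
composition), 6000 (ambiguous parent residue), 2000 (undetermined
attachment carbon), 0 (fully specified).  A glycan of *n* residues has
*n − 1* conceptual links whether or not any link is present; for *n* = 1
the link term contributes 0 and the weights are *not* renormalized.  The
0.40/0.60 split and the component table are this package's calibration of
the "~40% / ~60%" weighting; they pin the documented anchors exactly:

* fully defined → 0; multi-residue base composition → 10,000;
* lone superclass-only residue → 0.4 · 10000 = 4,000;
* lone stereo-only residue → 0.4 · 5000 = 2,000;
* two-residue composition (C1) → 0.4·5000 + 0.6·10000 = 8,000;
* two-residue topology with rings (T1) → 0.4·2500 + 0.6·2000 = 2,200.

Monotonicity: every degradation weakly increases every component and
strictly increases at least one, so the score strictly decreases along
every mass-preserving subsumption edge the generator can produce.  The one
unscored degree of freedom is substituent attachment position (an
undetermined-position variant scores the same); the fixture generator
never degrades substituents, so strictness holds on all generated
families.  Scores of structures without a subsumption relationship carry
no ordering guarantee.

## Composition strings and SNFG consistency

Residues map to composition names by superclass + modification kinds +
substituents (ring/anomer irrelevant); a deoxyhexose maps to Fuc only when
its galacto stereochemistry is present, else dHex; NeuAc/NeuGc/KDN by the
NON-acid-keto-deoxy pattern with/without the N-substituent.  Output order
is fixed — HexNAc, Hex, Fuc, dHex, NeuAc, NeuGc, KDN, HexA, Pent — with
zeros omitted.  The Byonic rendering is `Name(count)`; the single-letter
(`N4H5S2`) and UniCarbKB-style (`HexNAc4Hex5NeuAc2`) renderings are this
package's documented conventions (the letter map `SINGLE_LETTER` is the
remapping hook).  Unsupported inputs (linked structures, residues outside
the vocabulary, floating substituents) yield `None` rather than a wrong
name.  A Byonic parser is provided for composition lookup.

SNFG consistency checks every residue's stem+superclass+modification
descriptor and every substituent name against a whitelist TSV (columns
`name`, `glycoct_descriptor`, substituent rows prefixed `s:`); a default
whitelist covering the composition vocabulary plus sulfate/phosphate ships
with the package.

## Ontology export

OBO 1.2 flat file, chosen because it is self-contained to emit and to
validate with an independent reader (`obonet` in the tests); no OWL
toolchain is required.  Term scheme: structures use accession-based ids
(`GNO:<accession>`); the root glycan class, the category class, the five
category instances and the weight classes use permanent numeric ids
(weight classes numbered by ascending mass).  Term names use the Byonic
string when available, else `glycan <accession>`; weight classes are named
`glycan of molecular weight <X.XX> Da`.  `is_a` carries minimal
mass-preserving edges (falling back to the weight class, then the root);
`is_subsumed_by` carries all direct edges.  `has_topology` /
`has_composition` / `has_basecomposition` are emitted only when the derived
form exists in the DAG.  Obsolete accessions become obsolete terms with
`replaced_by` where known.  Browser deep-link predicates are emitted only
when a base URL is configured.  Output is byte-identical across runs.

**Restrictions** retain a member subset plus each member's archetype /
topology / composition / base-composition forms present in the primary
DAG; edges are the transitive reduction of the primary closure induced on
the retained nodes (mass-preserving iff the pair is connected in the
mass-preserving closure), and members carry `is_restriction_member`.

## Synthetic families

The fixture generator derives families from fully defined seeds (the
Gal(b1-4)GlcNAc disaccharide, a disialylated biantennary N-glycan, O-glycan
core 1 and core 2 fragments, single residues) by random chains of
information-removing degradations: drop one anomer, one ring, one
residue's stereochemistry, one link's parent positions, all links,
archetype the root, or reduce the root to the alditol.  Every step emits a
ground-truth edge (degraded subsumes input; for reduction, input subsumes
reduced, non-mass-preserving), so generator and engine check each other.
Alditol reduction is down-weighted so reduced structures stay a minority,
as in real registries.

What the families do *not* emulate: registry-scale structure counts, the
empirical distribution of characterization levels, esoteric
monosaccharides, substituent-position indeterminacy, and candidate-parent
topologies (expressible in the dialect and tested directly, but not
generated).  Passing tests therefore demonstrate correctness of the
machinery on the supported vocabulary, not coverage statistics of any
particular registry.

Default problem sizes — families of 50 variants, ten generator seeds per
seed structure (1,000 scored structures in the acceptance sweep), and
brute-force oracle comparison on ≤ 3-residue seeds — were chosen so the
exhaustive oracles stay exact while exercising every degradation kind.

## Degenerate inputs and tie-breaks

* Empty glycans are invalid; validation returns violation lists rather
  than raising, and every public operation validates first.
* Multi-residue link-free documents with a declared root are accepted
  (root information is simply unused by composition semantics).
* `x` positions and `-1` positions both parse as undetermined; writers
  emit `-1`.
* Candidate-parent links count as "undetermined" for the unmatched-link
  allowance and score 6000 regardless of position information, which keeps
  the penalty strictly between determined-parent (≤ 2000) and absent
  (10000).
* Within canonicalization, ties after refinement are broken by full
  serialization minimization, never by input order.

## Known limitations

* The subsumption matcher is exponential in the worst case; registry-scale
  weight groups with hundreds of near-identical topologies would need the
  symmetry-aware pruning that this package does not implement.
* Scores are calibrated to the documented anchors; other scoring
  component choices could satisfy the same anchors and order structures
  differently between anchors.
* No WURCS input, no repeating substructures, no subsumption across added
  substituents or monosaccharides (e.g. phosphate-added relationships).
* The OBO export does not aim to be a drop-in replacement for any released
  ontology's exact labels or numeric id assignments; ids are deterministic
  but local.
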