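# glysubsume

Glycan structure *subsumption*: a library and command-line tool that decides
when one partially characterized glycan description is consistent with — but
more general than — another, and organizes collections of glycan sequences
into a transitive-reduced subsumption DAG with characterization categories,
archetypes, 0–10,000 characterization scores, composition-string synonyms,
SNFG-consistency flags, restriction subsets, and an OBO-format ontology
export.

## The problem

Experimental glycan characterization is almost never complete: mass
spectrometry may establish only a monosaccharide composition, while detailed
biochemical analysis pins down linkage positions and anomeric
configurations.  Sequence formats such as GlycoCT record exactly which
details are known, so a registry of glycan sequences contains many
descriptions of "the same" molecule at different levels of detail.  The
subsumption partial order `a ⊃ b` — glycan description *a* subsumes *b* when
every piece of information in *a* is present and identical in *b* — makes
that structure explicit and navigable, and supports automated reasoning such
as propagating annotations from well-characterized structures to the
compositions that subsume them.

## The machinery

* **Pairwise subsumption** is decided by backtracking enumeration of
  subsumption-aware perfect matchings between the monosaccharides of the two
  structures, followed by a matching of their links: every link of the
  subsumed structure must be subsumed by a distinct link of the subsumer,
  while undetermined subsumer links may remain unmatched.  Compositions
  (link-free descriptions) subsume on a residue matching alone and are never
  subsumed by linked structures.  Floating substituents of the subsumer may
  match residue-attached substituents of the subsumed structure.
* **Collections** are grouped by underivatized monoisotopic mass (2
  decimals), aligned pairwise within each group, and reduced to the minimal
  edge set whose transitive closure is unchanged.  Alditol-reduced
  reducing-end structures are redundantly aligned into the weight group of
  their unreduced counterparts, yielding flagged non-mass-preserving edges.
* **Characterization levels** — Saccharide ⊐ Topology ⊐ Composition ⊐
  BaseComposition ⊐ MolecularWeight — classify each description, and the
  level operations (`topology_of`, `composition_of`, `basecomposition_of`,
  `archetype_of`) strip exactly the information not relevant to a level.
* **Scores**: a heuristic lack-of-characterization score in [0, 10,000],
  computed as `0.4 · mean(residue penalties) + 0.6 · mean(conceptual-link
  penalties)`, strictly monotone along mass-preserving subsumption edges.
* **Ontology export**: OBO 1.2 with `is_a` for mass-preserving edges,
  `is_subsumed_by` for all edges, molecular-weight class terms under a root
  glycan class, five subsumption-category named instances, and annotation
  predicates (`has_glytoucan_id`, `has_subsumption_category`,
  `has_topology`/`has_composition`/`has_basecomposition`,
  `has_Byonic_name`, `has_structure_characterization_score`, …).

Input is a documented GlycoCT-condensed dialect (see `docs/methods.md`);
GlyTouCan-style UND blocks and repeating units are rejected with explicit
errors.

## Worked example

```python
import glysubsume as gs
from glysubsume import fixtures as fx

F1 = fx.load_fixture("F1")          # fully defined Gal(b1-4)GlcNAc
print(gs.underivatized_mass(F1).monoisotopic_da)   # 383.1428
print(gs.category_of(F1).name)                     # Saccharide
print(gs.characterization_score(F1))               # 0.0

T1 = gs.topology_of(F1)             # anomers + linkage positions removed
C1 = gs.composition_of(F1)          # rings + links removed
B1 = gs.basecomposition_of(F1)      # stereochemistry removed
# categories: Topology, Composition, BaseComposition
# scores:     2200,     8000,        10000

dag = gs.build_dag([F1, T1, C1, B1], accessions=["GF1", "GT1", "GC1", "GB1"])
for e in sorted(dag.edges, key=lambda e: e.subsumer):
    print(e.subsumer, ">", e.subsumed)
# GB1 > GC1
# GC1 > GT1
# GT1 > GF1
print(gs.emit_obo(dag).count("[Instance]"))        # 5 category instances

NG = fx.load_fixture("NG")          # biantennary disialylated N-glycan
print(gs.composition_name(gs.composition_of(NG), "byonic"))
# HexNAc(4)Hex(5)NeuAc(2)
```

The six pairwise relationships of the chain collapse to the three minimal
edges shown; the scores decrease strictly from the base composition (10,000,
no information beyond residue counts) down to the fully defined structure
(0).  The same operations are available from the shell:

```sh
glysubsume score F1.glycoct                  # 0
glysubsume classify F1.glycoct               # Saccharide
glysubsume build --sequences seqs/ --out dag.json
glysubsume export-obo dag.json --out gno.obo
```

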