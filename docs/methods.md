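# Methods

## The EQ fragment

phenokit models a phenotype class as an equivalence axiom of the shape

```
has part some (Q and MODE some BEARER and has modifier some M [and towards some T])
```

with `MODE` one of `characteristic of` (the quality inheres in the bearer
itself) or `characteristic of part of` (the quality inheres in the bearer or
one of its parts), `BEARER` an atomic class optionally refined by
`occurs in some L` (for process bearers localized to an anatomical entity)
or `has role some R` (chemical-role context), and `M` an explicit
abnormal/normal modifier CURIE.  Exactly one quality per definition; unions,
negation and cardinality are outside the fragment.  The textual grammar is
Manchester-style; multi-word labels are single-quoted; `qualifier` is
accepted on input as an alias of the canonical `has modifier` relation, and
`inheres in` / `inheres in part of` as historical synonyms of the
characteristic-of relations.

## Ancestry semantics

All reasoning rests on one ancestry notion per slot:

* qualities and modifiers: reflexive-transitive `is_a` within the quality
  graph;
* bearers under part-of mode: reflexive-transitive closure over the union of
  `is_a` and `part_of`, i.e. property-chain semantics where mixed chains
  count (`is_a∘part_of → part_of` and conversely).  This is what licenses
  "increased thickness of the aortic valve leaflet ⊑ heart morphology
  phenotype": thickness is a morphology, and the leaflet is part of the
  valve, which is part of the heart;
* bearers under plain mode, `towards` and `has role` fillers: `is_a` only.
  No relation-ontology property chain composes `towards` or `has role` with
  `part_of`, so extending them would assert inferences the semantics does
  not support;
* `occurs in` locations: `is_a`+`part_of` (occurs-in does compose with
  part-of).

Obsolete terms are excluded from closures by default.  Dangling references
are collected into a validation report rather than being fatal (species
ontologies routinely cite external ids); a strict flag upgrades them to hard
errors.

## Structural subsumption

`eq_subsumes(sub, sup)` holds iff every slot of `sub` is at least as
specific as the corresponding slot of `sup` under the ancestries above.
Plain mode in the superclass requires plain mode in the subclass (being a
characteristic *of* X is a special case of being a characteristic of a
*part of* X, not vice versa).  One refinement matters for composite
bearers: when the superclass bearer carries an `occurs in` or `has role`
clause, the bearer-entity check is restricted to `is_a` even under part-of
mode.  In canonical-model terms, the located (or role-bearing) witness is
the bearer individual itself; the canonical individuals of its whole-of
ancestors carry no location or role edges, so allowing part-of ancestry
there would claim subsumptions a complete EL reasoner refutes.  The test
suite checks exact agreement between this decision procedure and an
independent model-enumeration oracle (canonical-model saturation under
`characteristic_of ⊑ characteristic_of_part_of` and
`characteristic_of_part_of ∘ part_of ⊑ characteristic_of_part_of`) over a
full toy universe and one hundred random reference universes; no divergence
is tolerated.

## Hierarchy construction

`classify` computes all pairwise subsumptions among the input terms,
collapses mutually subsuming definitions into equivalence classes, takes
the transitive reduction (networkx) of the strict subsumption DAG over
class representatives, and attaches the remaining members directly beneath
their representative.  The representative of an equivalence class is the
smallest member designated as a species-neutral grouping term when one is
present, else the lexicographically smallest id.  This choice is
deliberate: species-specific terms whose definitions coincide with a
grouping class are kept as *children* of that class rather than merged or
re-rooted under whichever species id happens to sort first — the hierarchy
exists to group species terms under species-neutral vocabulary, and an
equivalence report preserves the information that the definitions are
logically identical.  Manually asserted (child, parent) edges from a
sidecar table supplement inference for grouping classes that resist simple
EQ definition; terms with neither a definition nor an asserted parent are
placed under the phenotype root and flagged.  Cycles (possible only through
bad asserted input) are detected and refused.

## Pattern templates and id minting

Templates are a DOSDP subset: printf-style `%s` slots in the label,
definition and synonym texts, substituted positionally in each field's
`vars` order; a logical-definition template in the same Manchester grammar;
declared classes/relations; per-template contributor ORCIDs preserved
verbatim.  Fillers are validated against their declared range by reflexive
`is_a` closure only.  English articles ("increased size of **the** heart")
live in the template text; no label post-processing is attempted.  Filler
labels come from the reference ontology's primary label; a missing label is
an error rather than a CURIE fallback.

Minted ids are `prefix:zero-padded(base + sha256(pattern_id | sorted
binding) mod span)`, linearly probed past occupied ids, with the
key→id ledger persisted beside outputs so later runs (or runs over grown
filler tables) mint identically.  Worked-example grouping classes are
pinned to their canonical ids through the minter's override table.

## Cross-species mapping

Logical matching emits a cross-species exact-match row exactly when two
normalized definitions are field-identical after species anatomy ids are
rewritten through a functional bridge table.  Confidence defaults: 1.0 for
logical matches, 0.9 for label–label lexical matches, 0.7 when a synonym is
involved, 0.8 for the optional broad/narrow near-miss rows (definitions
identical except qualities in strict ancestor relation, off by default).
These confidences are declared configuration defaults of this
implementation, not measured quantities.  The same (subject, object) pair
found by both routes yields two rows with distinct justifications, matching
the one-justification-per-row exchange model; manually curated rows take
precedence over derived rows on conflict.  The SSSOM writer emits a
commented YAML header (curie map, set id, license) and a fixed column
order; read∘write is lossless including confidence at full float precision.

## Information content and similarity

`IC(t) = -log2(n(t)/N)` bits, where `n(t)` counts distinct genes annotated
to `t` or any hierarchy descendant (ancestor propagation) and `N` is the
count at the root; hence `IC(root) = 0` and IC is monotone non-decreasing
along descent.  Log base 2 is a declared choice (bits).  Terms with no
propagated annotation inherit the IC of their least-frequent annotated
ancestor and are flagged as fallbacks rather than silently patched.
Pairwise similarity: ancestor-set Jaccard over the classified hierarchy;
the most informative common ancestor (ties broken to the smallest id); and
the combined score `sqrt(jaccard × IC(MICA)/IC_max)` — one published
variant of the PhenoDigm family, isolated behind a single function so
alternatives are pluggable.  Profile similarity is the symmetric best-match
average; empty profiles score 0.

## Synthetic study conditions

The fixture bundle stands in for the real reference and species ontologies
at desk scale, and its defaults are the study conditions for every test:

* reference graphs: a quality hierarchy with
  quality > morphology > {size > increased/decreased size, thickness >
  increased thickness} plus amount, process-quality and a deliberately
  pattern-free "fragility" branch; an anatomy graph with heart, aortic
  valve part_of heart, a leaflet part_of the valve, forelimb zeugopod and
  ten further organs; mini process/cell/chemical graphs; a fish-local
  anatomy bridged to the neutral anatomy.  Identifiers that are fixed
  points of the public phenomics landscape keep their canonical CURIEs;
  all other ids are minted in a fixture-local `EX:` namespace.
* template library: 15 patterns spanning anatomy, process (including a
  two-variable localized-process pattern), cell, chemical and relational
  (`towards`) categories.
* species ontologies: human-, mouse- and fish-like, each carrying the
  enlarged-heart trio (one shared increased-size-of-heart definition; the
  fish bearer uses the bridged fish heart id) and the forelimb-zeugopod /
  forearm pair defined on the same anatomy id, plus 10 randomized terms
  split 0.6/0.3/0.1 across the conformance categories
  (pattern-conformant EQ / EQ but not pattern-conformant / no logical
  definition).
* annotation corpus: by default 60 genes, 2 annotations each, drawn over
  hierarchy leaves with Zipf weight `1/rank^1.2` (a long-tailed popularity
  profile typical of annotation databases), then topped up so every leaf
  has at least one annotation.

Regeneration with the same seed is byte-identical, file for file.  What the
synthetic conditions do **not** emulate: the scale of real phenotype
ontologies (tens of thousands of terms), lexical noise and synonym
richness, multiple-inheritance-heavy anatomies, incomplete bridge coverage,
and annotation biases beyond a stationary Zipf profile.  Passing tests
demonstrate the correctness of the machinery on exactly specified inputs,
not coverage statistics of any real ontology release.

## Numerical and procedural choices

* Deterministic everywhere: sorted iteration orders, seeded `random.Random`
  with integer seeds only (never seeded from strings, whose hashes are
  process-dependent), atomic file writes, repr-precision floats in SSSOM.
* Similarity tables sort by subject then descending score; score threshold
  is inclusive (`>=`).
* Equivalence-class reports, orphan lists and rejected-filler rows are
  emitted as TSV next to the main outputs.
* Problem sizes used by the shipped reproduction script: the full fixture
  bundle (48 generated terms, three 12-ish-term species ontologies, a
  60-gene corpus); the reasoner-oracle comparisons in the test-suite run a
  60-definition toy universe exhaustively plus 100 random 30-definition
  universes.  These sizes were chosen so that every check is exhaustive at
  its scale rather than sampled.

## Known limitations

* The structural reasoner is complete only for the implemented fragment; it
  does not unfold defined classes inside fillers, and general OWL features
  (GCIs, unions, negation, cardinality, data properties) are out of scope.
* Cell-proliferation-style patterns that need an acts-on-population-of
  relation are noted but not implemented.
* Lexical matching is exact string equality after case-folding,
  punctuation stripping and whitespace collapse — no stemming or embedding
  similarity.
* Conformance checking matches template *shapes*; a definition that is
  logically equivalent to a pattern instance but syntactically different
  (e.g. plain mode where the pattern uses part-of mode) counts as
  non-conformant, mirroring how pattern-adherence audits work in practice.
* The id-minting ledger resolves hash collisions by probing, so id
  stability across runs relies on persisting the ledger when filler tables
  grow.
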