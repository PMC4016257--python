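# phenoeq

Decompose **pre-composed** phenotype ontology concepts into **post-composed
Entity–Quality (EQ) statements**, and grade the result against manually
curated gold standards.

Species-specific phenotype ontologies (MP for mouse, HPO for human, ...)
name each phenotype as a single pre-composed concept such as *enlarged
dorsal root ganglion*. Cross-species phenotype integration instead uses the
EQ formalism, in which a phenotype is an **entity** — an anatomical
structure (MA/FMA) or biological process (GO) — described by a **quality**
(PATO): `E = dorsal root ganglion (MA:0000232)`, `Q = enlarged`. Curating
EQ statements by hand is slow; `phenoeq` derives candidate statements
automatically from the concept labels alone, for curators to confirm, and
ships the evaluation harness needed to measure how often the automatic
decomposition reproduces the curated one.

The pipeline is purely lexical:

1. **Normalization** — replace every character outside `[a-zA-Z0-9]` with a
   space, lowercase, drop stop words, Porter-stem each token.
2. **Dictionary annotation** — per-ontology lexicons built from normalized
   labels (and synonyms) are matched against every contiguous stem
   subsequence of the phenotype label; overlapping hits are allowed.
3. **Containment filtering** — annotations whose token span lies strictly
   inside a longer annotation's span are removed (the PATO hit *dorsal*
   disappears when *dorsal root ganglion* matched).
4. **Quality cross products** — quality concept B is a component of quality
   concept A when the stem set of one of B's terms is a subset of the stem
   set of one of A's terms (so *decreased depth* decomposes into
   *decreased* + *depth*); at combination time a group of quality
   annotations that exactly covers a composite's stem set is replaced by
   the composite.
5. **EQ assembly + replacement rules** — annotations become entity/quality
   sets by source namespace; rules rewrite qualities the way curators
   compose them (*absent* → *lacks all parts of type* unconditionally;
   optional conditional rules such as "label contains `increased … number`"
   → *has extra parts of type*).
6. **Evaluation** — generated statements are graded against gold in tiers:
   `exact` (set equality, label-based), `exact_synonym` (equality via a
   phenotype synonym), `relaxed` (gold ⊆ generated; surplus assignments are
   cheap for a curator to strike), then `partial` / `disjoint` /
   `not_transformed`.

## Worked example

```sh
phenoeq fixtures --out corpus --seed 3 \
    --plant "exact=4,exact_synonym=2,relaxed=2,partial=1,disjoint=2,not_transformed=1"
phenoeq decompose --phenotypes corpus/phenotypes.obo --anatomy corpus/anatomy.obo \
    --process corpus/process.obo --quality corpus/quality.obo --out eq.tsv
phenoeq evaluate --generated eq.tsv --gold corpus/gold.tsv --out eval.tsv \
    --sample 2 --seed 0
```

prints

```
wrote fixture corpus (seed 3, 12 phenotypes) to corpus
transformed 11 of 12 phenotypes -> eq.tsv
not transformed: 1
selected: 12  transformed: 11
exact: 4 (33.3% of selected)
exact_synonym: 2 (16.7% of selected)
relaxed: 2 (16.7% of selected)
partial: 1 (8.3% of selected)
disjoint: 2 (16.7% of selected)
not_transformed: 1 (8.3% of selected)
disjoint sample (2): PHEN:0000010 PHEN:0000011
```

The fixture generator planted each phenotype into a known category
(`exact=4`, `disjoint=2`, ...), and the pipeline recovers exactly those
counts: 11 of 12 labels produced an EQ statement (the one built from
unknown vocabulary did not), 4 match the gold statement exactly from the
label, 2 more exactly via a synonym, 2 need the relaxed criterion, and the
2 planted disjoint cases are the audit sample of statements sharing nothing
with the curator's.

The same pipeline runs unchanged on real OBO files
(`--phenotypes mp.obo --anatomy ma.obo --process go.obo --quality pato.obo`),
and `phenoeq crossproducts --quality pato.obo --out cp.tsv` exports the
quality composition table on its own.

As a library:

```python
from phenoeq import *

onto = Ontology("PATO")
onto.add(Concept(id="PATO:0001472", label="decreased depth"))
onto.add(Concept(id="PATO:0001997", label="decreased"))
onto.add(Concept(id="PATO:0001595", label="depth"))
derive_cross_products(onto)["PATO:0001472"].component_ids
# frozenset({'PATO:0001997', 'PATO:0001595'})
```

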