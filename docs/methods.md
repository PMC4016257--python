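# Methods

## The decomposition model

`phenoeq` treats the transformation of a pre-composed phenotype concept into
an Entity–Quality statement as a purely lexical problem: the concept label
is assumed to *contain* the names of the affected entity and of the
describing quality, possibly inflected, reordered relative to the source
ontologies' conventions, or interleaved with stop words. No ontology graph
structure (is_a hierarchy, relationships) is consulted anywhere; this is a
deliberate assumption of the method, which is why the data model keeps only
id, label, synonyms and the obsolete flag per concept.

The pipeline stages and their contracts:

- **Character filter.** Every character outside `[a-zA-Z0-9]` becomes a
  single space, and the text is lowercased. A closed character class is
  used instead of an inventory of "special characters" so the rule is total
  and order-independent. Numerals are kept as tokens: phenotype labels
  use them meaningfully ("4th finger").
- **Stop words.** A small pinned default list (`the of in a an to and or
  with for on by`) is bundled and can be replaced by file
  (`--stop-words`, one token per line, `#` comments). Matching quality is
  sensitive to this list, which is why it is pinned rather than taken from
  a large general-purpose inventory.
- **Stemming.** The classic Porter (1980) algorithm, implemented in
  `phenoeq/porter.py` and frozen against the algorithm's published
  word/stem examples. Stemming is applied identically to dictionary terms
  and phenotype labels, which recovers singular/plural and derivational
  variation (*abnormality*/*abnormalities*, *zorblat*/*zorblats*). It does
  **not** recover suppletive-ish Latin plurals in general; whether e.g.
  *vertebra*/*vertebrae* unify is an accident of the suffix rules, and the
  pipeline never assumes they do. A `use_stemming=False` switch exists
  throughout so the contribution of stemming can be measured; it is not
  intended for production runs.

- **Annotation.** One lexicon per source ontology, keyed by the
  space-joined stem sequence of each normalized term; obsolete concepts are
  excluded, terms normalizing to nothing are skipped with a warning, and a
  phrase shared by several concepts maps to all of them (ambiguity is kept
  for the curator). Labels are short (rarely more than ten informative
  tokens), so recognition simply hashes every contiguous stem subsequence
  against every lexicon — O(n²) lookups per label — rather than running a
  multi-pattern automaton. Spans are token-indexed, 0-based, half-open,
  which keeps containment well-defined after stop-word removal.
- **Containment filter.** An annotation is removed iff another annotation's
  span contains it strictly (equal spans all survive). The filter is
  applied uniformly across all namespaces, including the process ontology.
- **Cross products.** Component derivation uses stem *sets* (duplicates
  collapsed) and considers every term (label and synonyms) of both whole
  and component. The derivation is index-accelerated; an exhaustive
  pairwise oracle with the same semantics lives in `fixtures` and the two
  are asserted equal on seeded ontologies. Combination requires an *exact*
  cover — the union of the candidate annotations' span stems must equal one
  of the whole's term stem sets, nothing missing and nothing left over —
  which prevents a lone *decreased* from being promoted to *decreased
  depth*. Wholes are tried largest-stem-set-first with ties broken by id
  (determinism); a whole whose stem set is strictly contained in an
  already-emitted whole's is treated as subsumed, while two wholes that are
  each exactly covered are both emitted as alternatives. A cover consisting
  of a single annotation is an alternative reading of that span, so the
  single annotation is kept alongside the emitted whole rather than
  consumed; multi-annotation covers replace their parts.
- **Replacement rules.** Rules live in an ordered, human-editable YAML
  file; application order is file order and the bundled set is idempotent.
  The bundled unconditional rule rewrites *absent* (PATO:0000462) to *lacks
  all parts of type* (PATO:0002000). Conditional rules (off by default,
  `--conditional-rules`) trigger on a token pattern over the normalized
  label with at most one `*` gap wildcard; the bundled set maps the
  `increased activity` phrase to *increased rate* (PATO:0000912) and
  `increased … number` to *has extra parts of type* (PATO:0002001). Their
  `decreased` mirrors ship with the trigger only — no replacement id is
  bundled — and stay inert until the user supplies one. Pattern words are
  normalized with the pipeline's own stemmer, and rules whose ids belong to
  a different quality namespace than the loaded quality ontology are
  dropped at load time (they could never fire); a same-namespace
  replacement id absent from the ontology is an error.

- **Evaluation.** Matching is set-based per phenotype; multiple gold rows
  for one phenotype are merged by set union before comparison. The exact
  tier is reserved for label-based statements; synonym-derived statements
  (including the fallback primary used when the label yields nothing) are
  graded in the synonym tier, which therefore *augments* the exact tier and
  never replaces it — cumulative counts exact ≤ exact+synonym ≤
  relaxed-or-better are monotone by construction and asserted in tests.
  Because published corpus percentages are quoted against different
  denominators in different places, the report always carries both
  denominators (all selected phenotypes; transformed phenotypes only),
  explicitly labelled. The disjoint category — a generated statement
  sharing no concept with gold — is what the mismatch audit samples
  (seeded, uniform) are drawn from; whether a disjoint statement is truly
  "useless" is a curator judgment the package does not make.

## Synthetic corpora

The fixture generator (`phenoeq.fixtures`) is first-class, tested code and
the package's test bed. It emulates the lexical phenomena the method must
survive: labels composed verbatim as quality-phrase + entity-phrase,
synonyms, plural suffixes, multi-word anatomical terms that lexically
contain a quality term (the *dorsal root ganglion* situation), composite
qualities whose label is the concatenation of their components' labels
(guaranteeing the subset property the cross-product derivation looks for),
one synonym shared by two concepts, and the same label duplicated across
two entity ontologies. Each phenotype is planted into a known evaluation
category — exact, exact-via-synonym, relaxed-only, partial, disjoint,
untransformable — so the full pipeline's category counts can be checked
against the construction plan exactly.

Vocabulary is pronounceable CV-syllable nonsense minted from the seed,
guaranteed stem-unique and disjoint from the stop-word list; generation is
a pure function of the FixtureSpec (same seed ⇒ byte-identical files). Default
corpus sizes (a dozen entities, eight simple + four composite qualities,
twenty phenotypes; 100–200 phenotypes in the acceptance runs) keep every
check well under a minute while exercising all code paths.

What passing on these corpora does *not* show: real MP/HPO labels carry
naming-convention divergence (named vs numbered fingers), contractions
(*coat* for *coat hair*), missing process synonyms, and gold-standard
errors, none of which the clean fixtures reproduce. Corpus-scale accuracy
percentages on real ontologies depend on the ontology and gold-file
versions used and must be measured against the user's own downloads; the
package reports them but does not assert them.

## Numerical and design choices

- Determinism everywhere: lexicon iteration, whole ordering, cover
  enumeration, file writing (sorted ids, `\n` newlines) and sampling
  (explicit seeds) are all deterministic; identical configuration
  reproduces byte-identical outputs for every command.
- Degenerate inputs: labels normalizing to nothing are "not transformed";
  empty ontologies yield empty lexicons/maps/reports; an evaluation over
  zero phenotypes reports zero counts and 0% everywhere (no division by
  zero).
- Gold statements must carry at least one quality; entity-free gold
  statements are accepted with a warning (they exist in practice).
- The tabular ontology dialect sanitizes tabs/pipes inside labels to a
  single space on write, keeping the format unambiguous at the cost of
  perfect round-tripping for such labels.
- Entity/quality role is decided purely by the namespace of the matched
  concept's ontology, mirroring one dictionary per source ontology.

## Known limitations

- No relational qualities (E–Q–E2, "towards" a second entity) and no
  ontology-specific rewrite packs (e.g. *irregular* → *irregular density*);
  both are out of scope.
- No fuzzy or learned matching: a term absent from the dictionaries (or
  differing beyond what stemming unifies) is simply missed.
- One statement per phenotype holding *sets* of alternatives, rather than
  an enumeration of all candidate statements; this matches the relaxed
  evaluation semantics but discards co-occurrence structure between
  alternative entities and qualities.
- Porter stemming is not idempotent on arbitrary strings; both sides of
  every lookup are stemmed exactly once, so this never affects matching.
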