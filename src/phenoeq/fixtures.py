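"""Deterministic synthetic fixtures: toy ontologies, phenotype corpora and
gold EQ files with planted structure.

The generator emulates the lexical phenomena the decomposition method has
to cope with: labels composed as quality-phrase + entity-phrase, synonyms,
singular/plural variants, multi-word anatomical terms that lexically
contain quality terms, and composite qualities whose stemmed tokens are the
union of their components' tokens.  Every phenotype is planted into a known
evaluation category, so the full pipeline's output can be checked against
the construction recipe.  Everything is a pure function of the FixtureSpec
(identical seed ⇒ byte-identical files).

Synthetic vocabulary is pronounceable nonsense drawn from a seeded
generator, guaranteed stem-unique and disjoint from the stop-word list, so
fixtures cannot collide with bundled resources.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from pathlib import Path

from .normalize import DEFAULT_STOP_WORDS, normalize
from .ontology import (Concept, GoldEQ, Ontology, write_gold_eq, write_obo)
from .porter import porter_stem

__all__ = ["NoiseFlags", "FixtureSpec", "Fixture", "build_fixture",
           "generate_fixture", "brute_force_cross_products"]

ANATOMY_NS = "ANAT"
PROCESS_NS = "PROC"
QUALITY_NS = "QUAL"
PHENOTYPE_NS = "PHEN"

#: planted category keys, in construction order
PLANT_ORDER = ("exact", "exact_synonym", "relaxed", "partial", "disjoint",
               "not_transformed")


@dataclass(frozen=True)
class NoiseFlags:
    """Optional lexical noise emulating real-corpus mismatch classes."""

    plural_suffix: bool = False          # vertebra vs vertebrae
    synonym_label_swap: bool = False     # phenotype uses the entity's synonym
    contraction: bool = False            # "coat" for "coat hair"
    shared_synonym: bool = False         # one synonym on two concepts
    cross_namespace_duplicate: bool = False  # same label in two ontologies


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_entities: int = 12
    n_processes: int = 4
    n_qualities: int = 8
    n_composite_qualities: int = 4
    n_phenotypes: int = 20
    with_synonyms: bool = True
    noise: NoiseFlags = field(default_factory=NoiseFlags)
    #: category → count; None plants everything as "exact"
    planted_categories: dict[str, int] | None = None

    def plan(self) -> dict[str, int]:
        plan = dict(self.planted_categories) if self.planted_categories \
            else {"exact": self.n_phenotypes}
        for cat, cnt in plan.items():
            if cat not in PLANT_ORDER:
                raise ValueError(f"unknown planted category {cat!r}")
            if cnt < 0:
                raise ValueError("planted counts must be non-negative")
        if sum(plan.values()) != self.n_phenotypes:
            raise ValueError("planted category counts must sum to n_phenotypes")
        return plan

    def validate(self) -> None:
        for name in ("n_entities", "n_processes", "n_qualities",
                     "n_composite_qualities", "n_phenotypes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        plan = self.plan()
        needs_synonyms = (
            plan.get("exact_synonym", 0) > 0
            or self.noise.synonym_label_swap
            or self.noise.shared_synonym
        )
        if needs_synonyms and not self.with_synonyms:
            raise ValueError("synonym-based planting/noise requires with_synonyms")
        if self.n_composite_qualities > 0 and self.n_qualities < 2:
            raise ValueError("composite qualities need >= 2 simple qualities")
        if self.n_phenotypes > 0 and (self.n_entities < 2 or self.n_qualities < 2):
            raise ValueError("phenotype planting needs >= 2 entities and qualities")


@dataclass
class Fixture:
    anatomy: Ontology
    process: Ontology
    quality: Ontology
    phenotypes: Ontology
    gold: list[GoldEQ]


_CONSONANTS = "bcdfgklmnprtvz"
_VOWELS = "aiou"


class _WordMint:
    """Seeded generator of stem-unique nonsense words (CV syllables)."""

    def __init__(self, rng: random.Random):
        self.rng = rng
        self.used_stems = set(DEFAULT_STOP_WORDS)

    def word(self, syllables: int = 2) -> str:
        for _ in range(10_000):
            w = "".join(
                self.rng.choice(_CONSONANTS) + self.rng.choice(_VOWELS)
                for _ in range(syllables)
            )
            s = porter_stem(w)
            if s not in self.used_stems and w not in DEFAULT_STOP_WORDS:
                self.used_stems.add(s)
                return w
        raise RuntimeError("vocabulary exhausted")


def build_fixture(spec: FixtureSpec) -> Fixture:
    """Construct the fixture in memory (see module docstring for the planted
    label recipes)."""
    spec.validate()
    plan = spec.plan()
    rng = random.Random(spec.seed)
    mint = _WordMint(rng)

    # --- quality ontology: simple one-word qualities + composite wholes
    quality = Ontology(namespace=QUALITY_NS)
    q_words = [mint.word() for _ in range(spec.n_qualities)]
    simple_q: list[Concept] = []
    for i, w in enumerate(q_words, start=1):
        c = Concept(id=f"{QUALITY_NS}:{i:07d}", label=w)
        quality.add(c)
        simple_q.append(c)
    composite_q: list[Concept] = []
    pairs = list(itertools.combinations(range(len(q_words)), 2))
    if spec.n_composite_qualities > len(pairs):
        raise ValueError("not enough simple qualities for requested composites")
    for k, (i, j) in enumerate(pairs[: spec.n_composite_qualities], start=1):
        c = Concept(
            id=f"{QUALITY_NS}:{1000 + k:07d}",
            label=f"{q_words[i]} {q_words[j]}",
        )
        quality.add(c)
        composite_q.append(c)

    # --- anatomy: mostly single-word; the last entity (when room) is a
    # 3-token term whose first token is a quality word, exercising the
    # containment filter
    anatomy = Ontology(namespace=ANATOMY_NS)
    entities: list[Concept] = []
    for i in range(1, spec.n_entities + 1):
        if i == spec.n_entities and spec.n_entities >= 3 and q_words:
            label = f"{q_words[0]} {mint.word()} {mint.word()}"
        else:
            label = mint.word()
        synonyms = (mint.word(),) if spec.with_synonyms else ()
        c = Concept(id=f"{ANATOMY_NS}:{i:07d}", label=label, synonyms=synonyms)
        anatomy.add(c)
        entities.append(c)
    if spec.noise.shared_synonym and len(entities) >= 2:
        first = entities[0]
        second = entities[1]
        anatomy.concepts[second.id] = Concept(
            id=second.id, label=second.label,
            synonyms=second.synonyms + first.synonyms[:1],
        )
        entities[1] = anatomy.concepts[second.id]

    # --- processes
    process = Ontology(namespace=PROCESS_NS)
    processes: list[Concept] = []
    for i in range(1, spec.n_processes + 1):
        c = Concept(id=f"{PROCESS_NS}:{i:07d}", label=mint.word())
        process.add(c)
        processes.append(c)
    if spec.noise.cross_namespace_duplicate and processes and entities:
        dup = processes[0]
        process.concepts[dup.id] = Concept(
            id=dup.id, label=entities[0].label, synonyms=dup.synonyms,
        )
        processes[0] = process.concepts[dup.id]

    single_entities = [e for e in entities if " " not in e.label]

    # --- phenotypes + gold, per planted category
    phenotypes = Ontology(namespace=PHENOTYPE_NS)
    gold: list[GoldEQ] = []
    counter = itertools.count(1)

    def pick_quality() -> Concept:
        return rng.choice(simple_q + composite_q)

    def pluralize(label: str) -> str:
        return label + "s"

    for category in PLANT_ORDER:
        for _ in range(plan.get(category, 0)):
            pid = f"{PHENOTYPE_NS}:{next(counter):07d}"
            q = pick_quality()
            if category == "exact":
                e = rng.choice(entities)
                shown = e.label
                if spec.noise.synonym_label_swap and e.synonyms:
                    shown = e.synonyms[0]
                if spec.noise.contraction and " " in shown:
                    shown = shown.rsplit(" ", 1)[0]
                if spec.noise.plural_suffix:
                    shown = pluralize(shown)
                phenotypes.add(Concept(id=pid, label=f"{q.label} {shown}"))
                gold.append(GoldEQ(pid, frozenset({e.id}), frozenset({q.id})))
            elif category == "exact_synonym":
                e = rng.choice(single_entities)
                junk = mint.word()
                phenotypes.add(Concept(
                    id=pid,
                    label=f"{q.label} {junk}",
                    synonyms=(f"{q.label} {e.label}",),
                ))
                gold.append(GoldEQ(pid, frozenset({e.id}), frozenset({q.id})))
            elif category == "relaxed":
                e1, e2 = rng.sample(single_entities, 2)
                phenotypes.add(Concept(id=pid, label=f"{q.label} {e1.label} {e2.label}"))
                gold.append(GoldEQ(pid, frozenset({e1.id}), frozenset({q.id})))
            elif category == "partial":
                e1, e2 = rng.sample(single_entities, 2)
                phenotypes.add(Concept(id=pid, label=f"{q.label} {e1.label}"))
                gold.append(GoldEQ(pid, frozenset({e2.id}), frozenset({q.id})))
            elif category == "disjoint":
                q1, q2 = rng.sample(simple_q, 2)
                e1, e2 = rng.sample(single_entities, 2)
                phenotypes.add(Concept(id=pid, label=f"{q1.label} {e1.label}"))
                gold.append(GoldEQ(pid, frozenset({e2.id}), frozenset({q2.id})))
            else:  # not_transformed: only unknown vocabulary
                junk1, junk2 = mint.word(), mint.word()
                e = rng.choice(entities)
                phenotypes.add(Concept(id=pid, label=f"{junk1} {junk2}"))
                gold.append(GoldEQ(pid, frozenset({e.id}), frozenset({q.id})))

    return Fixture(anatomy=anatomy, process=process, quality=quality,
                   phenotypes=phenotypes, gold=gold)


def generate_fixture(spec: FixtureSpec, out_dir: str | Path) -> Fixture:
    """Write anatomy.obo, process.obo, quality.obo, phenotypes.obo and
    gold.tsv to *out_dir*; returns the in-memory fixture as well."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fx = build_fixture(spec)
    write_obo(fx.anatomy, out_dir / "anatomy.obo")
    write_obo(fx.process, out_dir / "process.obo")
    write_obo(fx.quality, out_dir / "quality.obo")
    write_obo(fx.phenotypes, out_dir / "phenotypes.obo")
    write_gold_eq(fx.gold, out_dir / "gold.tsv")
    return fx


def brute_force_cross_products(
    quality_ontology: Ontology,
    stop_words: frozenset[str] | set[str] = DEFAULT_STOP_WORDS,
    use_stemming: bool = True,
) -> dict[str, frozenset[str]]:
    """Test oracle: exhaustive pairwise subset check over all term pairs.

    Returns whole_id → component id set (wholes without components absent),
    computed by definition — for each ordered pair (A, B), B is a component
    of A iff the stem set of some term of B is a subset of the stem set of
    some term of A.
    """
    concepts = quality_ontology.active_concepts()

    def stem_sets(c: Concept) -> list[frozenset[str]]:
        out = []
        for term in c.terms(use_synonyms=True):
            stems = frozenset(normalize(term, stop_words, use_stemming).stems)
            if stems:
                out.append(stems)
        return out

    result: dict[str, frozenset[str]] = {}
    for a in concepts:
        components = set()
        for b in concepts:
            if b.id == a.id:
                continue
            hit = False
            for bs in stem_sets(b):
                for as_ in stem_sets(a):
                    if bs <= as_:
                        hit = True
            if hit:
                components.add(b.id)
        if components:
            result[a.id] = frozenset(components)
    return result
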