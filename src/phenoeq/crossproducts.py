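"""Quality cross products: term-wise composition of quality concepts.

A composite quality like "decreased depth" (PATO:0001472) can be expressed
through the component qualities "decreased" (PATO:0001997) and "depth"
(PATO:0001595).  Composition is purely lexical: after normalization and
stemming, concept B is a component of concept A whenever the stem set of one
of B's terms (label or synonym) is a subset of the stem set of one of A's
terms.  At annotation-combination time, a set of quality annotations is
replaced by the composite whole only when their stems exactly cover one of
the whole's term stem sets — no stem missing, none left over — which
prevents "decreased" alone from being promoted to "decreased depth".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .annotate import LABEL, SYNONYM, Annotation
from .normalize import DEFAULT_STOP_WORDS, NormalizedText, normalize
from .ontology import Ontology, curie_prefix

__all__ = ["CrossProduct", "derive_cross_products", "combine_annotations",
           "write_cross_products_tsv"]


@dataclass(frozen=True)
class CrossProduct:
    """A composite quality and the component qualities it decomposes into.

    ``whole_stems``/``via`` describe the primary (label) term; ``stem_sets``
    holds every candidate (via, stem set) pair, one per term of the whole,
    since a component may be licensed by a synonym of the whole rather than
    its label.
    """

    whole_id: str
    component_ids: frozenset[str]
    whole_stems: frozenset[str]
    via: str  # label | synonym — term that produced whole_stems
    stem_sets: tuple[tuple[str, frozenset[str]], ...] = ()

    def __post_init__(self) -> None:
        if self.whole_id in self.component_ids:
            raise ValueError(f"{self.whole_id} cannot be its own component")
        if not self.component_ids:
            raise ValueError(f"cross product for {self.whole_id} has no components")

    def candidate_stem_sets(self) -> tuple[frozenset[str], ...]:
        if self.stem_sets:
            return tuple(fs for _, fs in self.stem_sets)
        return (self.whole_stems,)


def _term_stem_sets(
    ontology: Ontology,
    stop_words: frozenset[str] | set[str],
    use_stemming: bool,
) -> dict[str, list[tuple[str, frozenset[str]]]]:
    """Per concept: [(via, stem set)] for label then synonyms, empties dropped."""
    out: dict[str, list[tuple[str, frozenset[str]]]] = {}
    for concept in ontology.active_concepts():
        sets: list[tuple[str, frozenset[str]]] = []
        for via, term in [(LABEL, concept.label)] + [(SYNONYM, s) for s in concept.synonyms]:
            stems = frozenset(normalize(term, stop_words, use_stemming).stems)
            if stems:
                sets.append((via, stems))
        if sets:
            out[concept.id] = sets
    return out


def derive_cross_products(
    quality_ontology: Ontology,
    stop_words: frozenset[str] | set[str] = DEFAULT_STOP_WORDS,
    use_stemming: bool = True,
) -> dict[str, CrossProduct]:
    """Find, for every quality concept, all other quality concepts whose
    stemmed terms form a subset of one of its stemmed terms.

    Wholes with no components are absent from the returned map.  Uses an
    inverted stem index to restrict the pairwise subset checks; the naive
    all-pairs oracle lives in :mod:`phenoeq.fixtures`.
    """
    term_sets = _term_stem_sets(quality_ontology, stop_words, use_stemming)

    index: dict[str, set[str]] = {}
    for cid, sets in term_sets.items():
        for _, stems in sets:
            for s in stems:
                index.setdefault(s, set()).add(cid)

    products: dict[str, CrossProduct] = {}
    for whole_id, whole_sets in term_sets.items():
        components: set[str] = set()
        for _, whole_stems in whole_sets:
            candidates = set().union(*(index.get(s, set()) for s in whole_stems))
            for cand in candidates:
                if cand == whole_id or cand in components:
                    continue
                if any(cs <= whole_stems for _, cs in term_sets[cand]):
                    components.add(cand)
        if components:
            via, primary = whole_sets[0]
            products[whole_id] = CrossProduct(
                whole_id=whole_id,
                component_ids=frozenset(components),
                whole_stems=primary,
                via=via,
                stem_sets=tuple(whole_sets),
            )
    return products


def _find_exact_cover(
    target: frozenset[str],
    pool: list[Annotation],
    label: NormalizedText,
) -> list[Annotation] | None:
    """First (smallest, then enumeration-order) subset of *pool* whose span
    stem sets union to exactly *target*."""
    usable = [
        a for a in pool
        if frozenset(label.stems[a.start:a.end]) <= target
    ]
    for size in range(1, len(usable) + 1):
        for combo in itertools.combinations(usable, size):
            union: set[str] = set()
            for a in combo:
                union.update(label.stems[a.start:a.end])
            if union == target:
                return list(combo)
    return None


def combine_annotations(
    annotations: list[Annotation],
    cross_products: dict[str, CrossProduct],
    label: NormalizedText,
    quality_ns: str | None = None,
) -> list[Annotation]:
    """Replace sets of quality annotations by composite-quality wholes where
    an exact stem cover exists.

    Non-quality annotations are never touched.  Wholes are tried
    largest-stem-set first (ties by id) so that components which are
    themselves composable are resolved greedily into the largest whole; a
    whole whose stem set is a strict subset of an already-emitted whole's is
    considered subsumed and skipped.  Two wholes that are each exactly
    covered (and neither subsumes the other) are both emitted as
    alternatives.
    """
    if not cross_products:
        return list(annotations)
    if quality_ns is None:
        quality_ns = curie_prefix(next(iter(cross_products)))

    quality = [a for a in annotations if a.namespace == quality_ns]
    others = [a for a in annotations if a.namespace != quality_ns]
    present_ids = {a.concept_id for a in quality}

    def whole_order(item: tuple[str, CrossProduct]) -> tuple[int, str]:
        cid, cp = item
        return (-max(len(fs) for fs in cp.candidate_stem_sets()), cid)

    consumed: set[int] = set()  # ids of consumed Annotation objects
    emitted: list[Annotation] = []
    emitted_sets: list[frozenset[str]] = []

    for whole_id, cp in sorted(cross_products.items(), key=whole_order):
        if whole_id in present_ids:
            continue  # already annotated directly; nothing to combine
        pool = [a for a in quality if a.concept_id != whole_id]
        for target in sorted(cp.candidate_stem_sets(), key=lambda fs: (-len(fs), sorted(fs))):
            if any(target < done for done in emitted_sets):
                continue  # subsumed by a larger whole already built
            cover = _find_exact_cover(target, pool, label)
            if cover is not None:
                start = min(a.start for a in cover)
                end = max(a.end for a in cover)
                emitted.append(Annotation(
                    phenotype_id=cover[0].phenotype_id,
                    start=start,
                    end=end,
                    concept_id=whole_id,
                    origin=cp.via,
                ))
                emitted_sets.append(target)
                if len(cover) > 1:
                    # a genuine composition replaces its parts; a single-
                    # annotation cover is an alternative reading of the same
                    # span, kept alongside the whole
                    consumed.update(id(a) for a in cover)
                break

    surviving = [a for a in quality if id(a) not in consumed]
    out = others + surviving + emitted
    out.sort(key=lambda a: (a.start, a.end, a.concept_id, a.origin))
    return out


def write_cross_products_tsv(products: dict[str, CrossProduct], path) -> None:
    """Export the cross-product table: whole_id, component_ids (pipe-
    separated), via."""
    import csv
    from pathlib import Path

    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["whole_id", "component_ids", "via"])
        for whole_id in sorted(products):
            cp = products[whole_id]
            writer.writerow([whole_id, "|".join(sorted(cp.component_ids)), cp.via])
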