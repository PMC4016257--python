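"""Dictionary-based concept recognition over normalized phenotype labels.

One lexicon is built per ontology from labels (and optionally synonyms),
keyed by the space-joined stem sequence of each normalized term.  Annotation
then tests every contiguous stem subsequence of a label against every
lexicon, which reproduces exhaustive dictionary tagging including
overlapping hits; a containment filter afterwards removes annotations whose
token span lies strictly inside a longer one (so "dorsal" disappears when
"dorsal root ganglion" matched).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .normalize import DEFAULT_STOP_WORDS, NormalizedText, normalize
from .ontology import Ontology, curie_prefix

logger = logging.getLogger(__name__)

__all__ = ["Lexicon", "Annotation", "build_lexicon", "annotate", "filter_contained"]

LABEL = "label"
SYNONYM = "synonym"


@dataclass(frozen=True)
class Annotation:
    """A recognized concept occurrence inside a phenotype label.

    ``start``/``end`` are 0-based half-open token indices into the
    normalized label.
    """

    phenotype_id: str
    start: int
    end: int
    concept_id: str
    origin: str  # label | synonym

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")
        if self.origin not in (LABEL, SYNONYM):
            raise ValueError(f"unknown origin {self.origin!r}")

    @property
    def namespace(self) -> str:
        return curie_prefix(self.concept_id)

    def span_length(self) -> int:
        return self.end - self.start

    def contains(self, other: "Annotation") -> bool:
        """Strict containment: other's span inside self's, self longer."""
        return (
            self.start <= other.start
            and other.end <= self.end
            and self.span_length() > other.span_length()
        )


@dataclass
class Lexicon:
    """Per-ontology dictionary: stemmed phrase → {(concept id, origin)}."""

    namespace: str
    entries: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def add(self, key: str, concept_id: str, origin: str) -> None:
        if not key:
            raise ValueError("empty lexicon key")
        self.entries.setdefault(key, set()).add((concept_id, origin))

    def __len__(self) -> int:
        return len(self.entries)


def build_lexicon(
    ontology: Ontology,
    use_synonyms: bool = True,
    stop_words: frozenset[str] | set[str] = DEFAULT_STOP_WORDS,
    use_stemming: bool = True,
) -> Lexicon:
    """Compile the dictionary from non-obsolete concept labels and, when
    *use_synonyms*, synonyms.  Terms that normalize to nothing (stop-word-only
    labels) are skipped with a warning."""
    lexicon = Lexicon(namespace=ontology.namespace)
    for concept in ontology.active_concepts():
        terms = [(concept.label, LABEL)]
        if use_synonyms:
            terms += [(s, SYNONYM) for s in concept.synonyms]
        for term, origin in terms:
            key = normalize(term, stop_words, use_stemming).stem_key
            if not key:
                logger.warning("term %r of %s normalizes to nothing; skipped",
                               term, concept.id)
                continue
            lexicon.add(key, concept.id, origin)
    return lexicon


def annotate(
    label: NormalizedText,
    lexicons: list[Lexicon],
    phenotype_id: str = "?:?",
) -> list[Annotation]:
    """Recognize concepts in *label* against every lexicon.

    Every contiguous stem subsequence matching a lexicon key yields one
    annotation per mapped concept id; hits from different lexicons (or the
    same one) may overlap or coincide.  The label must have been normalized
    with the same stop words and stemming switch as the lexicons.
    """
    stems = label.stems
    out: list[Annotation] = []
    for i in range(len(stems)):
        for j in range(i + 1, len(stems) + 1):
            key = " ".join(stems[i:j])
            for lexicon in lexicons:
                for concept_id, origin in sorted(lexicon.entries.get(key, ())):
                    out.append(Annotation(phenotype_id, i, j, concept_id, origin))
    return out


def filter_contained(annotations: list[Annotation]) -> list[Annotation]:
    """Remove annotations entirely included in a strictly longer one.

    Identical spans are all kept (ambiguity is preserved for the curator);
    the operation is idempotent.
    """
    return [
        a for a in annotations
        if not any(b.contains(a) for b in annotations)
    ]
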