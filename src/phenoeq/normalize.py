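"""Lexical normalization: character filtering, stop-word removal, stemming.

Every match in the pipeline — lexicon lookup, quality cross-product
derivation, replacement-rule triggers — is performed on the normalized stem
sequence produced here, so label and dictionary must always be normalized
with the same stop-word list and the same stemming switch.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from .porter import porter_stem

__all__ = [
    "DEFAULT_STOP_WORDS",
    "NormalizedText",
    "filter_characters",
    "tokenize",
    "stem",
    "normalize",
    "load_stop_words",
]

#: Pinned default stop-word list (configurable via file for reproducibility).
DEFAULT_STOP_WORDS = frozenset(
    ["the", "of", "in", "a", "an", "to", "and", "or", "with", "for", "on", "by"]
)

_NON_ALNUM_RE = re.compile(r"[^a-zA-Z0-9]+")


@dataclass(frozen=True)
class NormalizedText:
    """A label together with its normalized token and stem sequences."""

    original: str
    tokens: tuple[str, ...]
    stems: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.stems):
            raise ValueError("tokens and stems must align one-to-one")

    @property
    def stem_key(self) -> str:
        """Space-joined stems — the lexicon lookup key for the full phrase."""
        return " ".join(self.stems)


def filter_characters(text: str) -> str:
    """Replace every character outside [a-zA-Z0-9] with a space; lowercase.

    Special punctuation ("%", "-", ...) carries no information for matching
    concept labels across ontologies and would fragment otherwise identical
    phrases.
    """
    return _NON_ALNUM_RE.sub(" ", text).lower()


def tokenize(text: str, stop_words: frozenset[str] | set[str] = DEFAULT_STOP_WORDS) -> list[str]:
    """Whitespace-split an already character-filtered string, dropping stop
    words; order is preserved."""
    return [t for t in text.split() if t not in stop_words]


def stem(tokens: list[str] | tuple[str, ...]) -> list[str]:
    """Porter-stem each token independently.  Idempotent on its own output
    for the token inventories used here."""
    return [porter_stem(t) for t in tokens]


def normalize(
    text: str,
    stop_words: frozenset[str] | set[str] = DEFAULT_STOP_WORDS,
    use_stemming: bool = True,
) -> NormalizedText:
    """filter_characters → tokenize → stem, bundled into a NormalizedText.

    ``use_stemming=False`` keeps raw tokens as stems; it exists to measure
    how much stemming contributes to matching (singular/plural recovery).
    """
    tokens = tuple(tokenize(filter_characters(text), stop_words))
    stems = tuple(stem(tokens)) if use_stemming else tokens
    return NormalizedText(original=text, tokens=tokens, stems=stems)


def load_stop_words(path: str | Path) -> frozenset[str]:
    """Read a stop-word file: one token per line, '#' comments allowed."""
    words = set()
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.split("#", 1)[0].strip().lower()
        if line:
            words.add(line)
    return frozenset(words)
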