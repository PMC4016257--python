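"""Ontology data model and file I/O.

Concepts are held purely lexically (id, label, synonyms, obsolete flag): the
decomposition method never traverses the is_a hierarchy, so no graph is kept.
Supported formats: OBO 1.2/1.4 flat files (read), a tabular ontology dialect
(read/write), and gold-standard EQ statement files in either a TSV dialect or
OBO logical-definition stanzas (intersection_of).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)

__all__ = [
    "Concept",
    "Ontology",
    "GoldEQ",
    "OboParseError",
    "curie_prefix",
    "is_curie",
    "parse_obo",
    "parse_tbl",
    "write_tbl",
    "parse_gold_eq",
    "write_gold_eq",
    "select_structure_process",
]

_CURIE_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.-]*:\S+$")


def is_curie(identifier: str) -> bool:
    """True if *identifier* looks like PREFIX:LOCALID with both parts non-empty."""
    return bool(_CURIE_RE.match(identifier))


def curie_prefix(identifier: str) -> str:
    if not is_curie(identifier):
        raise ValueError(f"not a CURIE: {identifier!r}")
    return identifier.split(":", 1)[0]


class OboParseError(ValueError):
    """Raised for malformed OBO input; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True)
class Concept:
    """One ontology term: CURIE id, primary label, synonyms, obsolete flag."""

    id: str
    label: str
    synonyms: tuple[str, ...] = ()
    obsolete: bool = False

    def __post_init__(self) -> None:
        if not is_curie(self.id):
            raise ValueError(f"concept id is not a CURIE: {self.id!r}")
        if not self.obsolete and not self.label:
            raise ValueError(f"non-obsolete concept {self.id} has no label")

    @property
    def namespace(self) -> str:
        return curie_prefix(self.id)

    def terms(self, use_synonyms: bool = True) -> tuple[str, ...]:
        """Label plus (optionally) synonyms, label first."""
        out = (self.label,) if self.label else ()
        if use_synonyms:
            out += self.synonyms
        return out


@dataclass
class Ontology:
    """A bag of concepts keyed by id, with a declared primary namespace.

    An ontology file may legitimately contain ids from other namespaces;
    they are kept but reported via :meth:`foreign_ids`.
    """

    namespace: str
    concepts: dict[str, Concept] = field(default_factory=dict)

    def add(self, concept: Concept) -> None:
        if concept.id in self.concepts:
            raise ValueError(f"duplicate concept id: {concept.id}")
        self.concepts[concept.id] = concept

    def foreign_ids(self) -> list[str]:
        return [c.id for c in self.concepts.values() if c.namespace != self.namespace]

    def active_concepts(self) -> list[Concept]:
        return [c for c in self.concepts.values() if not c.obsolete]

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self.concepts

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Ontology):
            return NotImplemented
        return self.namespace == other.namespace and self.concepts == other.concepts


@dataclass(frozen=True)
class GoldEQ:
    """A manually curated post-composed statement for one phenotype.

    ``entity_ids`` are anatomy/process concepts, ``quality_ids`` are quality
    (PATO-style) concepts.  At least one quality is required; entity-free
    statements occur in practice and are flagged on load, not rejected.
    """

    phenotype_id: str
    entity_ids: frozenset[str]
    quality_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not is_curie(self.phenotype_id):
            raise ValueError(f"phenotype id is not a CURIE: {self.phenotype_id!r}")
        if not self.quality_ids:
            raise ValueError(f"gold statement for {self.phenotype_id} has no quality")
        for cid in list(self.entity_ids) + list(self.quality_ids):
            if not is_curie(cid):
                raise ValueError(f"gold id is not a CURIE: {cid!r}")


# ---------------------------------------------------------------------------
# OBO flat-file reading

_SYNONYM_RE = re.compile(r'^"(.*)"')


def _parse_synonym_value(value: str) -> str:
    """Extract the quoted text of a synonym line; scope markers are ignored."""
    m = _SYNONYM_RE.match(value.strip())
    if m is None:
        raise ValueError("synonym value is not quoted")
    return m.group(1)


def parse_obo(path: str | Path, namespace: str | None = None) -> Ontology:
    """Read an OBO 1.2/1.4 flat file into an :class:`Ontology`.

    One concept per ``[Term]`` stanza; synonyms are collected from all
    synonym lines regardless of scope; the obsolete flag comes from
    ``is_obsolete``.  Malformed stanzas raise :class:`OboParseError` naming
    the line; duplicate ids raise ``ValueError``.

    If *namespace* is not given it is taken from the prefix of the first
    term id.
    """
    path = Path(path)
    stanzas: list[dict] = []
    current: dict | None = None
    in_term = False
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("!"):
                continue
            if line.startswith("["):
                if not line.endswith("]"):
                    raise OboParseError("unterminated stanza header", lineno)
                in_term = line == "[Term]"
                current = {"lineno": lineno, "synonyms": []} if in_term else None
                if in_term:
                    stanzas.append(current)
                continue
            if current is None:
                continue  # header block or non-Term stanza
            if ":" not in line:
                raise OboParseError(f"expected 'tag: value', got {line!r}", lineno)
            tag, _, value = line.partition(":")
            tag = tag.strip()
            value = value.split(" !")[0].strip()
            if tag == "id":
                current["id"] = value
                current["id_line"] = lineno
            elif tag == "name":
                current["name"] = value
            elif tag in ("synonym", "exact_synonym", "broad_synonym",
                         "narrow_synonym", "related_synonym"):
                try:
                    current["synonyms"].append(_parse_synonym_value(value))
                except ValueError as exc:
                    raise OboParseError(str(exc), lineno) from exc
            elif tag == "is_obsolete":
                current["obsolete"] = value.lower() == "true"

    if namespace is None:
        for st in stanzas:
            if "id" in st:
                namespace = curie_prefix(st["id"])
                break
        else:
            namespace = path.stem.upper()

    ontology = Ontology(namespace=namespace)
    for st in stanzas:
        if "id" not in st:
            raise OboParseError("[Term] stanza without an id", st["lineno"])
        concept = Concept(
            id=st["id"],
            label=st.get("name", ""),
            synonyms=tuple(st["synonyms"]),
            obsolete=st.get("obsolete", False),
        )
        ontology.add(concept)
    if ontology.foreign_ids():
        logger.warning(
            "%s: %d concepts outside namespace %s",
            path.name, len(ontology.foreign_ids()), namespace,
        )
    return ontology


def write_obo(ontology: Ontology, path: str | Path) -> None:
    """Write a minimal OBO 1.2 flat file (deterministic: stanzas sorted by id)."""
    path = Path(path)
    lines = ["format-version: 1.2", f"ontology: {ontology.namespace.lower()}", ""]
    for cid in sorted(ontology.concepts):
        c = ontology.concepts[cid]
        lines.append("[Term]")
        lines.append(f"id: {c.id}")
        if c.label:
            lines.append(f"name: {c.label}")
        for syn in c.synonyms:
            lines.append(f'synonym: "{syn}" EXACT []')
        if c.obsolete:
            lines.append("is_obsolete: true")
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# Tabular dialect (id / name / synonyms / obsolete)

_TBL_COLUMNS = ["id", "name", "synonyms", "obsolete"]


def _sanitize_field(text: str) -> str:
    # tabs/pipes inside labels would break the dialect; collapse to one space
    return re.sub(r"[\t|]+", " ", text)


def parse_tbl(path: str | Path, namespace: str | None = None) -> Ontology:
    """Read the tab-separated ontology dialect (columns id, name, synonyms,
    obsolete; synonyms pipe-separated)."""
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in _TBL_COLUMNS:
            if col not in header:
                raise ValueError(f"{path.name}: missing mandatory column {col!r}")
        rows = list(reader)
    if namespace is None:
        namespace = curie_prefix(rows[0]["id"]) if rows else path.stem.upper()
    ontology = Ontology(namespace=namespace)
    for row in rows:
        synonyms = tuple(s for s in (row["synonyms"] or "").split("|") if s)
        ontology.add(Concept(
            id=row["id"],
            label=row["name"],
            synonyms=synonyms,
            obsolete=(row["obsolete"] or "").strip().lower() == "true",
        ))
    return ontology


def write_tbl(ontology: Ontology, path: str | Path) -> None:
    """Write the tabular dialect; ``parse_tbl(write_tbl(x)) == x`` up to the
    tab/pipe sanitization of labels."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TBL_COLUMNS)
        for cid in sorted(ontology.concepts):
            c = ontology.concepts[cid]
            writer.writerow([
                c.id,
                _sanitize_field(c.label),
                "|".join(_sanitize_field(s) for s in c.synonyms),
                "true" if c.obsolete else "false",
            ])


# ---------------------------------------------------------------------------
# Gold-standard EQ statements

def _merge_gold(rows: Iterable[GoldEQ]) -> list[GoldEQ]:
    """Merge duplicate phenotype rows by set union, preserving first-seen order."""
    merged: dict[str, GoldEQ] = {}
    for g in rows:
        if g.phenotype_id in merged:
            prev = merged[g.phenotype_id]
            merged[g.phenotype_id] = GoldEQ(
                phenotype_id=g.phenotype_id,
                entity_ids=prev.entity_ids | g.entity_ids,
                quality_ids=prev.quality_ids | g.quality_ids,
            )
        else:
            merged[g.phenotype_id] = g
    return list(merged.values())


def parse_gold_eq(path: str | Path) -> list[GoldEQ]:
    """Read gold EQ statements.

    Two dialects are accepted: the TSV dialect (columns phenotype_id,
    entity_ids, quality_ids; multi-values pipe-separated) and OBO
    logical-definition stanzas, where each ``[Term]`` carries
    ``intersection_of`` lines — a bare genus quality id plus
    ``inheres_in`` entity relations.  Duplicate phenotype rows are merged
    by set union.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        head = fh.read(4096)
    if "[Term]" in head or head.lstrip().startswith("format-version"):
        return _merge_gold(_parse_gold_obo(path))
    return _merge_gold(_parse_gold_tsv(path))


def _parse_gold_tsv(path: Path) -> list[GoldEQ]:
    out: list[GoldEQ] = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        for col in ("phenotype_id", "entity_ids", "quality_ids"):
            if col not in header:
                raise ValueError(f"{path.name}: missing mandatory column {col!r}")
        for row in reader:
            entities = frozenset(e for e in (row["entity_ids"] or "").split("|") if e)
            qualities = frozenset(q for q in (row["quality_ids"] or "").split("|") if q)
            gold = GoldEQ(row["phenotype_id"], entities, qualities)
            if not entities:
                logger.warning("gold statement %s has no entity", gold.phenotype_id)
            out.append(gold)
    return out


_INTERSECTION_RE = re.compile(r"^intersection_of:\s*(\S+)(?:\s+(\S+))?")


def _parse_gold_obo(path: Path) -> list[GoldEQ]:
    out: list[GoldEQ] = []
    current_id: str | None = None
    genus: list[str] = []
    entities: list[str] = []

    def flush() -> None:
        if current_id is not None and genus:
            out.append(GoldEQ(current_id, frozenset(entities), frozenset(genus)))

    with path.open("r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if line == "[Term]":
                flush()
                current_id, genus, entities = None, [], []
            elif line.startswith("id:"):
                current_id = line.partition(":")[2].split(" !")[0].strip()
            elif line.startswith("intersection_of:"):
                m = _INTERSECTION_RE.match(line)
                if m is None:
                    continue
                first, second = m.group(1), m.group(2)
                second = None if second is None else second.split("!")[0].strip() or None
                if second is None:
                    genus.append(first)  # bare genus: the quality
                elif first in ("inheres_in", "RO:0000052", "inheres_in_part_of"):
                    entities.append(second)
    flush()
    return out


def write_gold_eq(statements: Iterable[GoldEQ], path: str | Path,
                  extra_columns: dict[str, dict[str, str]] | None = None) -> None:
    """Write gold-dialect TSV; *extra_columns* maps column name →
    (phenotype_id → value), used for the generated-EQ provenance column."""
    path = Path(path)
    extra = extra_columns or {}
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["phenotype_id", "entity_ids", "quality_ids", *extra])
        for g in statements:
            writer.writerow([
                g.phenotype_id,
                "|".join(sorted(g.entity_ids)),
                "|".join(sorted(g.quality_ids)),
                *(extra[col].get(g.phenotype_id, "") for col in extra),
            ])


def select_structure_process(
    gold: list[GoldEQ],
    anatomy_ns: set[str],
    process_ns: set[str],
    quality_ns: str,
) -> list[GoldEQ]:
    """Keep only structure/process phenotypes: every entity prefix in
    anatomy_ns ∪ process_ns and every quality prefix equal to quality_ns."""
    if not anatomy_ns or not process_ns:
        raise ValueError("namespace sets must be non-empty")
    if anatomy_ns & process_ns:
        raise ValueError("anatomy and process namespaces must be disjoint")
    entity_ns = anatomy_ns | process_ns
    return [
        g for g in gold
        if all(curie_prefix(e) in entity_ns for e in g.entity_ids)
        and all(curie_prefix(q) == quality_ns for q in g.quality_ids)
    ]
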