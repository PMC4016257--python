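"""Assembly of EQ statements from annotations, with quality replacement rules.

A phenotype's filtered and combined annotations are split by source
namespace: anatomy/process hits become the entity set, quality hits the
quality set.  Replacement rules then rewrite qualities the way curators
compose them — unconditionally (``absent`` is always written as ``lacks all
parts of type`` in curated statements) or conditionally on a token pattern
in the phenotype label (labels of the form "increased ... number" carry
``has extra parts of type`` rather than plain ``increased``).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import yaml

from .annotate import LABEL, SYNONYM, Annotation, Lexicon, annotate, filter_contained
from .crossproducts import CrossProduct, combine_annotations
from .normalize import DEFAULT_STOP_WORDS, NormalizedText, normalize
from .ontology import Concept, Ontology, curie_prefix

logger = logging.getLogger(__name__)

__all__ = [
    "EQStatement",
    "ReplacementRule",
    "load_rules",
    "bundled_rules_path",
    "compose_eq",
    "apply_replacements",
    "decompose_ontology",
    "decompose_label",
    "write_generated_eq",
    "parse_generated_eq",
]

GENERATED = "generated"
GOLD = "gold"


@dataclass(frozen=True)
class EQStatement:
    """A post-composed phenotype: entity concept(s) plus quality concept(s).

    ``alternatives`` holds statements derived from the phenotype's synonyms
    (when synonym decomposition is on); they augment rather than replace the
    label-based statement.  ``warnings`` records cross-namespace duplicate
    hits (the same span matched concepts from different ontologies).
    """

    phenotype_id: str
    entity_ids: frozenset[str]
    quality_ids: frozenset[str]
    provenance: str = GENERATED
    source_label_used: str = LABEL
    alternatives: tuple["EQStatement", ...] = ()
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class ReplacementRule:
    """Quality rewrite rule.

    Unconditional rules replace ``trigger_quality`` wherever it occurs.
    Conditional rules fire only when ``trigger_pattern`` (a token sequence
    with at most one ``*`` gap wildcard, matched over the normalized label)
    occurs; a conditional rule with no ``replacement_quality`` is inert —
    the trigger is known but the target id must be supplied by the user.
    """

    kind: str  # unconditional | conditional
    replacement_quality: str | None
    trigger_quality: str | None = None
    trigger_pattern: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("unconditional", "conditional"):
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if self.kind == "unconditional":
            if not self.trigger_quality:
                raise ValueError("unconditional rule needs trigger_quality")
            if not self.replacement_quality:
                raise ValueError("unconditional rule needs replacement_quality")
        else:
            if not self.trigger_pattern:
                raise ValueError("conditional rule needs a non-empty pattern")
            if list(self.trigger_pattern).count("*") > 1:
                raise ValueError("at most one gap wildcard allowed")
        if self.replacement_quality is not None and \
                self.replacement_quality == self.trigger_quality:
            raise ValueError("replacement must differ from trigger")

    @property
    def active(self) -> bool:
        return self.replacement_quality is not None


def bundled_rules_path() -> Path:
    """Path of the rule file shipped with the package."""
    return Path(str(resources.files("phenoeq").joinpath("data/rules.yaml")))


def load_rules(
    path: str | Path | None = None,
    quality_ontology: Ontology | None = None,
    include_conditional: bool = False,
) -> list[ReplacementRule]:
    """Load replacement rules from a YAML file (bundled set by default).

    Conditional rules are included only on request.  When
    *quality_ontology* is given, every replacement id must exist in it.
    """
    path = bundled_rules_path() if path is None else Path(path)
    data = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    rules: list[ReplacementRule] = []
    for entry in data.get("unconditional", []) or []:
        rules.append(ReplacementRule(
            kind="unconditional",
            trigger_quality=entry["trigger"],
            replacement_quality=entry["replacement"],
        ))
    if include_conditional:
        for entry in data.get("conditional", []) or []:
            rules.append(ReplacementRule(
                kind="conditional",
                trigger_quality=entry.get("trigger"),
                trigger_pattern=tuple(str(entry["pattern"]).split()),
                replacement_quality=entry.get("replacement"),
            ))
    if quality_ontology is not None:
        ns = quality_ontology.namespace
        kept: list[ReplacementRule] = []
        for rule in rules:
            rid = rule.replacement_quality
            trigger_ns = (curie_prefix(rule.trigger_quality)
                          if rule.trigger_quality else ns)
            if trigger_ns != ns or (rid is not None and curie_prefix(rid) != ns):
                # a rule for a different quality namespace can never fire here
                logger.info("dropping rule for foreign namespace: %s",
                            rule.trigger_quality or rule.trigger_pattern)
                continue
            if rid is not None and rid not in quality_ontology:
                raise ValueError(f"replacement quality {rid} not in ontology {ns}")
            kept.append(rule)
        rules = kept
    for rule in rules:
        if rule.kind == "conditional" and not rule.active:
            logger.info("conditional rule %s has no replacement id; inert",
                        " ".join(rule.trigger_pattern))
    return rules


def _pattern_matches(pattern: tuple[str, ...], label: NormalizedText,
                     stop_words: frozenset[str] | set[str],
                     use_stemming: bool) -> bool:
    """Match a token pattern (≤1 '*' gap) against the label's stems.

    Pattern words go through the same normalization as the label so that
    "increased activity" also matches "increased activities".
    """
    if "*" in pattern:
        gap = pattern.index("*")
        before, after = pattern[:gap], pattern[gap + 1:]
    else:
        before, after = pattern, ()
    norm = lambda ws: tuple(normalize(" ".join(ws), stop_words, use_stemming).stems)
    before, after = norm(before), norm(after)
    stems = label.stems

    def find_from(sub: tuple[str, ...], lo: int) -> int:
        if not sub:
            return lo
        for i in range(lo, len(stems) - len(sub) + 1):
            if tuple(stems[i:i + len(sub)]) == sub:
                return i + len(sub)
        return -1

    pos = find_from(before, 0)
    if pos < 0:
        return False
    return find_from(after, pos) >= 0


def apply_replacements(
    eq: EQStatement,
    label: NormalizedText,
    rules: list[ReplacementRule],
    stop_words: frozenset[str] | set[str] = DEFAULT_STOP_WORDS,
    use_stemming: bool = True,
) -> EQStatement:
    """Apply rules in file order; idempotent for the bundled rule set."""
    qualities = set(eq.quality_ids)
    for rule in rules:
        if not rule.active:
            continue
        if rule.kind == "unconditional":
            if rule.trigger_quality in qualities:
                qualities.discard(rule.trigger_quality)
                qualities.add(rule.replacement_quality)
        else:
            if rule.trigger_quality in qualities and _pattern_matches(
                    rule.trigger_pattern, label, stop_words, use_stemming):
                qualities.discard(rule.trigger_quality)
                qualities.add(rule.replacement_quality)
    if qualities == set(eq.quality_ids):
        return eq
    return replace(eq, quality_ids=frozenset(qualities))


def compose_eq(
    phenotype: Concept,
    annotations: list[Annotation],
    quality_ns: str,
    source_label_used: str = LABEL,
) -> EQStatement | None:
    """Build the EQ statement from surviving annotations; ``None`` when the
    phenotype produced no annotation at all (counts as not transformed)."""
    if not annotations:
        return None
    entities = frozenset(a.concept_id for a in annotations
                         if a.namespace != quality_ns)
    qualities = frozenset(a.concept_id for a in annotations
                          if a.namespace == quality_ns)
    return EQStatement(
        phenotype_id=phenotype.id,
        entity_ids=entities,
        quality_ids=qualities,
        source_label_used=source_label_used,
        warnings=_duplication_warnings(phenotype.id, annotations),
    )


def _duplication_warnings(phenotype_id: str,
                          annotations: list[Annotation]) -> tuple[str, ...]:
    """Flag identical spans matched by concepts from different namespaces
    (non-orthogonal ontologies duplicating a concept)."""
    by_span: dict[tuple[int, int], set[str]] = {}
    ids_by_span: dict[tuple[int, int], set[str]] = {}
    for a in annotations:
        by_span.setdefault((a.start, a.end), set()).add(a.namespace)
        ids_by_span.setdefault((a.start, a.end), set()).add(a.concept_id)
    out = []
    for span in sorted(by_span):
        if len(by_span[span]) > 1:
            out.append(
                f"{phenotype_id}: span {span[0]}..{span[1]} matched by "
                + ", ".join(sorted(ids_by_span[span]))
            )
    return tuple(out)


def decompose_label(
    phenotype: Concept,
    text: str,
    lexicons: list[Lexicon],
    cross_products: dict[str, CrossProduct],
    rules: list[ReplacementRule],
    quality_ns: str,
    stop_words: frozenset[str] | set[str] = DEFAULT_STOP_WORDS,
    use_stemming: bool = True,
    source_label_used: str = LABEL,
) -> EQStatement | None:
    """Run the full per-label pipeline:
    normalize → annotate → filter_contained → combine → compose → replace."""
    label = normalize(text, stop_words, use_stemming)
    if not label.tokens:
        return None
    anns = annotate(label, lexicons, phenotype_id=phenotype.id)
    anns = filter_contained(anns)
    anns = combine_annotations(anns, cross_products, label, quality_ns=quality_ns)
    eq = compose_eq(phenotype, anns, quality_ns, source_label_used)
    if eq is None:
        return None
    return apply_replacements(eq, label, rules, stop_words, use_stemming)


def decompose_ontology(
    phenotypes: Ontology,
    lexicons: list[Lexicon],
    cross_products: dict[str, CrossProduct],
    rules: list[ReplacementRule],
    use_synonyms: bool = False,
    quality_ns: str = "PATO",
    stop_words: frozenset[str] | set[str] = DEFAULT_STOP_WORDS,
    use_stemming: bool = True,
) -> dict[str, EQStatement]:
    """Decompose every non-obsolete phenotype concept.

    When *use_synonyms*, the phenotype's synonyms are decomposed too; their
    statements ride along as ``alternatives`` of the primary statement (or
    become the primary when the label itself yields nothing).  Phenotypes
    with no statement from any term are omitted from the map.
    """
    out: dict[str, EQStatement] = {}
    for pid in sorted(phenotypes.concepts):
        phenotype = phenotypes.concepts[pid]
        if phenotype.obsolete:
            continue
        primary = decompose_label(
            phenotype, phenotype.label, lexicons, cross_products, rules,
            quality_ns, stop_words, use_stemming, source_label_used=LABEL,
        )
        synonym_eqs: list[EQStatement] = []
        if use_synonyms:
            for syn in phenotype.synonyms:
                eq = decompose_label(
                    phenotype, syn, lexicons, cross_products, rules,
                    quality_ns, stop_words, use_stemming,
                    source_label_used=SYNONYM,
                )
                if eq is not None:
                    synonym_eqs.append(eq)
        if primary is None and synonym_eqs:
            primary = replace(synonym_eqs[0], alternatives=tuple(synonym_eqs[1:]))
        elif primary is not None and synonym_eqs:
            primary = replace(primary, alternatives=tuple(synonym_eqs))
        if primary is not None:
            out[pid] = primary
    logger.info("transformed %d of %d phenotypes",
                len(out), len(phenotypes.active_concepts()))
    return out


# ---------------------------------------------------------------------------
# Generated-EQ TSV (gold layout plus provenance/source columns)

_GEN_COLUMNS = ["phenotype_id", "entity_ids", "quality_ids", "provenance", "source"]


def write_generated_eq(generated: dict[str, EQStatement], path: str | Path) -> None:
    """Write generated statements (one row per statement; synonym
    alternatives get their own rows)."""
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_GEN_COLUMNS)
        for pid in sorted(generated):
            eq = generated[pid]
            for stmt in (eq, *eq.alternatives):
                writer.writerow([
                    stmt.phenotype_id,
                    "|".join(sorted(stmt.entity_ids)),
                    "|".join(sorted(stmt.quality_ids)),
                    stmt.provenance,
                    stmt.source_label_used,
                ])


def parse_generated_eq(path: str | Path) -> dict[str, EQStatement]:
    """Inverse of :func:`write_generated_eq`."""
    rows_by_pid: dict[str, list[EQStatement]] = {}
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for col in _GEN_COLUMNS:
            if col not in (reader.fieldnames or []):
                raise ValueError(f"missing mandatory column {col!r}")
        for row in reader:
            stmt = EQStatement(
                phenotype_id=row["phenotype_id"],
                entity_ids=frozenset(e for e in row["entity_ids"].split("|") if e),
                quality_ids=frozenset(q for q in row["quality_ids"].split("|") if q),
                provenance=row["provenance"],
                source_label_used=row["source"],
            )
            rows_by_pid.setdefault(stmt.phenotype_id, []).append(stmt)
    out: dict[str, EQStatement] = {}
    for pid, stmts in rows_by_pid.items():
        out[pid] = replace(stmts[0], alternatives=tuple(stmts[1:]))
    return out
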