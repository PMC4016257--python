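"""Grading generated EQ statements against curated gold statements.

Matching is tiered.  *Exact* requires set equality of entities and of
qualities for the label-based statement; *exact via synonym* grants the
same equality to a statement derived from one of the phenotype's synonyms;
*relaxed* tolerates extra generated concepts (the gold sets must be subsets
of the generated ones — a curator can strike surplus assignments cheaply).
Below those: *partial* (some shared concept), *disjoint* (a statement
exists but shares nothing with gold), *not transformed* (no statement at
all).  Every selected phenotype lands in exactly one category.
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass, field
from pathlib import Path

from .compose import EQStatement
from .ontology import GoldEQ

__all__ = [
    "EXACT", "EXACT_SYNONYM", "RELAXED", "PARTIAL", "DISJOINT", "NOT_TRANSFORMED",
    "CATEGORIES", "MatchResult", "EvaluationReport",
    "match_eq", "evaluate_corpus", "sample_mismatches",
    "synonym_map", "write_evaluation_tsv",
]

EXACT = "exact"
EXACT_SYNONYM = "exact_synonym"
RELAXED = "relaxed"
PARTIAL = "partial"
DISJOINT = "disjoint"
NOT_TRANSFORMED = "not_transformed"

CATEGORIES = (EXACT, EXACT_SYNONYM, RELAXED, PARTIAL, DISJOINT, NOT_TRANSFORMED)

# rank for picking the best classification among candidates
_RANK = {EXACT: 0, RELAXED: 1, PARTIAL: 2, DISJOINT: 3}


@dataclass(frozen=True)
class MatchResult:
    phenotype_id: str
    category: str
    shared_entities: frozenset[str] = frozenset()
    shared_qualities: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass
class EvaluationReport:
    """Corpus-level tallies plus per-phenotype results."""

    counts: dict[str, int]
    results: list[MatchResult]
    n_selected: int
    n_transformed: int
    duplication_warnings: list[str] = field(default_factory=list)

    def percentage(self, category: str, denominator: str = "selected") -> float:
        denom = self.n_selected if denominator == "selected" else self.n_transformed
        return 100.0 * self.counts.get(category, 0) / denom if denom else 0.0

    def cumulative(self) -> dict[str, int]:
        """Cumulative match counts: exact ≤ +synonym ≤ +relaxed."""
        e = self.counts.get(EXACT, 0)
        s = e + self.counts.get(EXACT_SYNONYM, 0)
        r = s + self.counts.get(RELAXED, 0)
        return {"exact": e, "exact_plus_synonym": s, "relaxed_or_better": r}


def _classify(generated: EQStatement, gold: GoldEQ) -> str:
    ge, gq = generated.entity_ids, generated.quality_ids
    if ge == gold.entity_ids and gq == gold.quality_ids:
        return EXACT
    if gold.entity_ids <= ge and gold.quality_ids <= gq:
        return RELAXED
    if (ge & gold.entity_ids) or (gq & gold.quality_ids):
        return PARTIAL
    return DISJOINT


def match_eq(generated: EQStatement, gold: GoldEQ, mode: str = "exact") -> MatchResult:
    """Compare one generated statement against gold.

    ``mode="exact"`` reports EXACT only on set equality; ``mode="relaxed"``
    additionally accepts gold ⊆ generated (reported as RELAXED).  Below the
    requested tier the result degrades to partial/disjoint as appropriate.
    """
    if generated.phenotype_id != gold.phenotype_id:
        raise ValueError(
            f"phenotype mismatch: {generated.phenotype_id} vs {gold.phenotype_id}"
        )
    if mode not in ("exact", "relaxed"):
        raise ValueError(f"unknown mode {mode!r}")
    category = _classify(generated, gold)
    if category == RELAXED and mode == "exact":
        # the extra assignments disqualify it from an exact match; it still
        # shares concepts, so under the strict tier it counts as partial
        category = PARTIAL
    return MatchResult(
        phenotype_id=gold.phenotype_id,
        category=category,
        shared_entities=frozenset(generated.entity_ids & gold.entity_ids),
        shared_qualities=frozenset(generated.quality_ids & gold.quality_ids),
    )


def synonym_map(generated: dict[str, EQStatement]) -> dict[str, tuple[EQStatement, ...]]:
    """Project the synonym-derived candidate statements out of a
    decomposition map (for the synonym tier of evaluate_corpus)."""
    out: dict[str, tuple[EQStatement, ...]] = {}
    for pid, eq in generated.items():
        candidates = tuple(s for s in (eq, *eq.alternatives)
                           if s.source_label_used == "synonym")
        if candidates:
            out[pid] = candidates
    return out


def _best(generated: EQStatement | tuple[EQStatement, ...] | None,
          gold: GoldEQ) -> tuple[str | None, EQStatement | None]:
    """Best classification over one statement or a tuple of candidates."""
    if generated is None:
        return None, None
    candidates = generated if isinstance(generated, tuple) else (generated,)
    best: tuple[str, EQStatement] | None = None
    for stmt in candidates:
        cat = _classify(stmt, gold)
        if best is None or _RANK[cat] < _RANK[best[0]]:
            best = (cat, stmt)
    return best if best is not None else (None, None)


def evaluate_corpus(
    generated: dict[str, EQStatement],
    gold: list[GoldEQ],
    synonyms_generated: dict[str, tuple[EQStatement, ...]] | None = None,
) -> EvaluationReport:
    """Grade the whole corpus.

    *gold* should already be restricted to structure/process phenotypes.
    Category ladder per phenotype: exact (label) → exact via synonym →
    relaxed → partial → disjoint → not transformed.  Percentages are
    reported over both denominators (all selected phenotypes; transformed
    only).
    """
    synonyms_generated = synonyms_generated or {}
    counts = {c: 0 for c in CATEGORIES}
    results: list[MatchResult] = []
    warnings: list[str] = []
    n_transformed = 0

    for g in gold:
        label_stmt = generated.get(g.phenotype_id)
        syn_stmts = synonyms_generated.get(g.phenotype_id)
        if label_stmt is not None:
            warnings.extend(label_stmt.warnings)
        if label_stmt is None and not syn_stmts:
            counts[NOT_TRANSFORMED] += 1
            results.append(MatchResult(g.phenotype_id, NOT_TRANSFORMED))
            continue
        n_transformed += 1

        # the exact tier is reserved for label-based decomposition; synonym-
        # derived statements (fallback primaries, alternatives) grade in the
        # synonym tier
        label_cands: list[EQStatement] = []
        syn_cands: list[EQStatement] = []
        if label_stmt is not None:
            for s in (label_stmt, *label_stmt.alternatives):
                (syn_cands if s.source_label_used == "synonym"
                 else label_cands).append(s)
        for s in syn_stmts or ():
            if s not in syn_cands:
                syn_cands.append(s)

        cat_l, stmt_l = _best(tuple(label_cands) or None, g)
        cat_s, stmt_s = _best(tuple(syn_cands) or None, g)

        if cat_l == EXACT:
            category, stmt = EXACT, stmt_l
        elif cat_s == EXACT:
            category, stmt = EXACT_SYNONYM, stmt_s
        else:
            pick = min(
                (c for c in (cat_l, cat_s) if c is not None),
                key=_RANK.__getitem__,
            )
            stmt = stmt_l if cat_l == pick else stmt_s
            category = pick
        results.append(MatchResult(
            phenotype_id=g.phenotype_id,
            category=category,
            shared_entities=frozenset(stmt.entity_ids & g.entity_ids),
            shared_qualities=frozenset(stmt.quality_ids & g.quality_ids),
        ))
        counts[category] += 1

    assert sum(counts.values()) == len(gold)
    return EvaluationReport(
        counts=counts,
        results=results,
        n_selected=len(gold),
        n_transformed=n_transformed,
        duplication_warnings=warnings,
    )


def sample_mismatches(report: EvaluationReport, n: int, seed: int) -> list[MatchResult]:
    """Uniform sample of *n* disjoint-category results (the audit set: cases
    where method and curator share no concept); all of them if fewer exist."""
    if n < 0:
        raise ValueError("n must be >= 0")
    disjoint = sorted(
        (r for r in report.results if r.category == DISJOINT),
        key=lambda r: r.phenotype_id,
    )
    if n >= len(disjoint):
        return disjoint
    return random.Random(seed).sample(disjoint, n)


def write_evaluation_tsv(
    report: EvaluationReport,
    path: str | Path,
    generated: dict[str, EQStatement] | None = None,
    gold: list[GoldEQ] | None = None,
) -> None:
    """Write the per-concept evaluation file with a commented summary block."""
    gold_by_id = {g.phenotype_id: g for g in (gold or [])}
    generated = generated or {}
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        fh.write(f"# selected_phenotypes\t{report.n_selected}\n")
        fh.write(f"# transformed_phenotypes\t{report.n_transformed}\n")
        for cat in CATEGORIES:
            fh.write(
                f"# {cat}\t{report.counts.get(cat, 0)}"
                f"\t{report.percentage(cat, 'selected'):.1f}% of selected"
                f"\t{report.percentage(cat, 'transformed'):.1f}% of transformed\n"
            )
        for w in report.duplication_warnings:
            fh.write(f"# duplication_warning\t{w}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow([
            "phenotype_id", "category",
            "generated_entities", "generated_qualities",
            "gold_entities", "gold_qualities",
            "shared_entities", "shared_qualities",
        ])
        for r in sorted(report.results, key=lambda r: r.phenotype_id):
            eq = generated.get(r.phenotype_id)
            g = gold_by_id.get(r.phenotype_id)
            writer.writerow([
                r.phenotype_id, r.category,
                "|".join(sorted(eq.entity_ids)) if eq else "",
                "|".join(sorted(eq.quality_ids)) if eq else "",
                "|".join(sorted(g.entity_ids)) if g else "",
                "|".join(sorted(g.quality_ids)) if g else "",
                "|".join(sorted(r.shared_entities)),
                "|".join(sorted(r.shared_qualities)),
            ])
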