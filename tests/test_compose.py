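"""EQ assembly, replacement rules, whole-ontology decomposition."""

import pytest

from phenoeq.annotate import build_lexicon
from phenoeq.compose import (EQStatement, ReplacementRule, apply_replacements,
                             compose_eq, decompose_label, decompose_ontology,
                             load_rules, parse_generated_eq, write_generated_eq)
from phenoeq.crossproducts import derive_cross_products
from phenoeq.fixtures import (FixtureSpec, PHENOTYPE_NS, QUALITY_NS,
                              build_fixture)
from phenoeq.normalize import normalize
from phenoeq.ontology import Concept, Ontology


def _lexicons(fx, use_synonyms=True):
    return [build_lexicon(fx.anatomy, use_synonyms),
            build_lexicon(fx.process, use_synonyms),
            build_lexicon(fx.quality, use_synonyms)]


def test_compose_eq_worked_example(anatomy_small, quality_small):
    phenotype = Concept(id="MP:0008490", label="enlarged dorsal root ganglion")
    eq = decompose_label(
        phenotype, phenotype.label,
        [build_lexicon(anatomy_small), build_lexicon(quality_small)],
        {}, [], quality_ns="PATO")
    assert eq.entity_ids == {"MA:0000232"}
    assert eq.quality_ids == {"PATO:0000600"}


def test_compose_eq_none_without_annotations():
    phenotype = Concept(id="MP:1", label="whatever")
    assert compose_eq(phenotype, [], quality_ns="PATO") is None


def test_unconditional_absent_replacement(quality_small):
    rules = load_rules(quality_ontology=quality_small)
    eq = EQStatement("MP:1", frozenset(), frozenset({"PATO:0000462"}))
    label = normalize("absent spleen")
    replaced = apply_replacements(eq, label, rules)
    assert replaced.quality_ids == {"PATO:0002000"}
    # idempotent for the bundled rule set
    assert apply_replacements(replaced, label, rules) == replaced


def test_conditional_increased_number_rule(quality_small):
    rules = load_rules(quality_ontology=quality_small, include_conditional=True)
    label = normalize("increased lumbar vertebrae number")
    eq = EQStatement("MP:0004650", frozenset({"MA:0000312"}),
                     frozenset({"PATO:0000470"}))
    replaced = apply_replacements(eq, label, rules)
    assert replaced.quality_ids == {"PATO:0002001"}
    assert apply_replacements(replaced, label, rules) == replaced


def test_conditional_increased_activity_rule(quality_small):
    rules = load_rules(quality_ontology=quality_small, include_conditional=True)
    # the trigger phrase must occur contiguously (stop words removed)
    label = normalize("increased activity of neurons")
    eq = EQStatement("MP:0006038", frozenset(), frozenset({"PATO:0000470"}))
    assert apply_replacements(eq, label, rules).quality_ids == {"PATO:0000912"}


def test_conditional_rule_needs_pattern_match(quality_small):
    rules = load_rules(quality_ontology=quality_small, include_conditional=True)
    label = normalize("increased size")  # no "number"/"activity" in label
    eq = EQStatement("MP:1", frozenset(), frozenset({"PATO:0000470"}))
    assert apply_replacements(eq, label, rules) == eq


def test_decreased_rules_ship_inert(quality_small):
    rules = load_rules(quality_ontology=quality_small, include_conditional=True)
    inert = [r for r in rules if not r.active]
    assert inert and all(r.trigger_pattern[0] == "decreased" for r in inert)
    label = normalize("decreased lumbar vertebrae number")
    eq = EQStatement("MP:1", frozenset(), frozenset({"PATO:0001997"}))
    assert apply_replacements(eq, label, rules) == eq


def test_empty_rule_list_is_noop():
    eq = EQStatement("MP:1", frozenset(), frozenset({"PATO:0000462"}))
    assert apply_replacements(eq, normalize("absent spleen"), []) == eq


def test_rule_with_unknown_replacement_rejected_at_load(tmp_path, quality_small):
    path = tmp_path / "rules.yaml"
    path.write_text(
        "unconditional:\n- trigger: PATO:0000462\n  replacement: PATO:9999999\n",
        encoding="utf-8")
    with pytest.raises(ValueError, match="PATO:9999999"):
        load_rules(path, quality_ontology=quality_small)


def test_rule_invariants():
    with pytest.raises(ValueError):
        ReplacementRule(kind="unconditional", trigger_quality="PATO:1",
                        replacement_quality="PATO:1")
    with pytest.raises(ValueError):
        ReplacementRule(kind="conditional", trigger_pattern=("a", "*", "b", "*"),
                        replacement_quality="PATO:2")


def test_decompose_round_trip_on_constructed_labels():
    fx = build_fixture(FixtureSpec(seed=7, n_phenotypes=20))
    generated = decompose_ontology(
        fx.phenotypes, _lexicons(fx), derive_cross_products(fx.quality), [],
        quality_ns=QUALITY_NS)
    assert len(generated) == 20
    gold_by_id = {g.phenotype_id: g for g in fx.gold}
    for pid, eq in generated.items():
        assert eq.entity_ids == gold_by_id[pid].entity_ids
        assert eq.quality_ids == gold_by_id[pid].quality_ids


def test_decompose_empty_ontology():
    assert decompose_ontology(Ontology(PHENOTYPE_NS), [], {}, []) == {}


def test_decompose_omits_stop_word_only_labels(quality_small):
    phen = Ontology("MP")
    phen.add(Concept(id="MP:1", label="of the"))
    generated = decompose_ontology(phen, [build_lexicon(quality_small)], {}, [],
                                   quality_ns="PATO")
    assert generated == {}


def test_decompose_synonyms_transform_superset():
    fx = build_fixture(FixtureSpec(seed=5, n_phenotypes=12, planted_categories={
        "exact": 6, "exact_synonym": 4, "not_transformed": 2}))
    products = derive_cross_products(fx.quality)
    without = decompose_ontology(fx.phenotypes, _lexicons(fx), products, [],
                                 use_synonyms=False, quality_ns=QUALITY_NS)
    with_syn = decompose_ontology(fx.phenotypes, _lexicons(fx), products, [],
                                  use_synonyms=True, quality_ns=QUALITY_NS)
    assert set(without) <= set(with_syn)


def test_generated_eq_tsv_round_trip(tmp_path):
    fx = build_fixture(FixtureSpec(seed=2, n_phenotypes=8, planted_categories={
        "exact": 5, "exact_synonym": 3}))
    generated = decompose_ontology(
        fx.phenotypes, _lexicons(fx), derive_cross_products(fx.quality), [],
        use_synonyms=True, quality_ns=QUALITY_NS)
    path = tmp_path / "eq.tsv"
    write_generated_eq(generated, path)
    parsed = parse_generated_eq(path)
    assert set(parsed) == set(generated)
    for pid in generated:
        assert parsed[pid].entity_ids == generated[pid].entity_ids
        assert parsed[pid].quality_ids == generated[pid].quality_ids
        assert len(parsed[pid].alternatives) == len(generated[pid].alternatives)
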