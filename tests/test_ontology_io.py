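"""OBO / tabular / gold-standard file I/O."""

import pytest
from hypothesis import given, settings, strategies as st

from phenoeq.fixtures import FixtureSpec, build_fixture
from phenoeq.ontology import (Concept, GoldEQ, OboParseError, Ontology, is_curie,
                              parse_gold_eq, parse_obo, parse_tbl,
                              select_structure_process, write_obo, write_tbl)

OBO_SAMPLE = """format-version: 1.2

[Term]
id: PATO:0001472
name: decreased depth
synonym: "reduced depth" EXACT []

[Term]
id: PATO:0001997
name: decreased
is_obsolete: true

[Typedef]
id: part_of
name: part of
"""


def test_parse_obo_basic(tmp_path):
    path = tmp_path / "q.obo"
    path.write_text(OBO_SAMPLE, encoding="utf-8")
    onto = parse_obo(path)
    assert onto.namespace == "PATO"
    assert len(onto) == 2  # Typedef stanza ignored
    c = onto.concepts["PATO:0001472"]
    assert c.label == "decreased depth"
    assert c.synonyms == ("reduced depth",)
    assert not c.obsolete
    assert onto.concepts["PATO:0001997"].obsolete


def test_parse_obo_empty_header_only(tmp_path):
    path = tmp_path / "empty.obo"
    path.write_text("format-version: 1.2\n", encoding="utf-8")
    assert len(parse_obo(path, namespace="X")) == 0


def test_parse_obo_counts_obsolete(tmp_path):
    onto = Ontology("T")
    for i in range(10):
        onto.add(Concept(id=f"T:{i:07d}", label=f"term {i}", obsolete=i < 3))
    path = tmp_path / "t.obo"
    write_obo(onto, path)
    parsed = parse_obo(path)
    assert len(parsed) == 10
    assert sum(c.obsolete for c in parsed.concepts.values()) == 3


def test_parse_obo_malformed_stanza_names_line(tmp_path):
    path = tmp_path / "bad.obo"
    path.write_text("[Term]\nid: A:1\nname no colon here\n", encoding="utf-8")
    with pytest.raises(OboParseError, match="line 3"):
        parse_obo(path)


def test_parse_obo_duplicate_id_rejected(tmp_path):
    path = tmp_path / "dup.obo"
    path.write_text("[Term]\nid: A:1\nname: x\n\n[Term]\nid: A:1\nname: y\n",
                    encoding="utf-8")
    with pytest.raises(ValueError, match="duplicate"):
        parse_obo(path)


def test_parse_obo_agrees_with_obonet(tmp_path):
    """Independent cross-check of the OBO reader against obonet."""
    obonet = pytest.importorskip("obonet")
    path = tmp_path / "fx.obo"
    write_obo(build_fixture(FixtureSpec(seed=3)).quality, path)
    ours = parse_obo(path)
    graph = obonet.read_obo(str(path), ignore_obsolete=False)
    assert set(graph.nodes) == set(ours.concepts)
    for node, data in graph.nodes(data=True):
        assert data.get("name", "") == ours.concepts[node].label


def test_tbl_round_trip_and_examples(tmp_path):
    path = tmp_path / "o.tbl"
    path.write_text(
        "id\tname\tsynonyms\tobsolete\n"
        "MP:0002895\tabnormal otolithic membrane\t\tfalse\n"
        "MP:0000001\tmammalian phenotype\ta|b\tfalse\n",
        encoding="utf-8",
    )
    onto = parse_tbl(path)
    assert onto.concepts["MP:0002895"].label == "abnormal otolithic membrane"
    assert onto.concepts["MP:0000001"].synonyms == ("a", "b")

    out = tmp_path / "rt.tbl"
    write_tbl(onto, out)
    assert parse_tbl(out) == onto


def test_tbl_missing_column(tmp_path):
    path = tmp_path / "bad.tbl"
    path.write_text("id\tname\n", encoding="utf-8")
    with pytest.raises(ValueError, match="synonyms"):
        parse_tbl(path)


def test_write_tbl_sanitizes_tabs_and_pipes(tmp_path):
    onto = Ontology("X")
    onto.add(Concept(id="X:1", label="a\tb", synonyms=("c|d",)))
    path = tmp_path / "s.tbl"
    write_tbl(onto, path)
    parsed = parse_tbl(path)
    assert parsed.concepts["X:1"].label == "a b"
    assert parsed.concepts["X:1"].synonyms == ("c d",)


_word = st.text(alphabet="abcdefghij", min_size=1, max_size=6)


@given(st.lists(st.tuples(st.integers(0, 999), _word,
                          st.lists(_word, max_size=2), st.booleans()),
                max_size=8, unique_by=lambda t: t[0]))
@settings(max_examples=50, derandomize=True)
def test_tbl_round_trip_property(tmp_path_factory, rows):
    onto = Ontology("Z")
    for num, label, synonyms, obsolete in rows:
        onto.add(Concept(id=f"Z:{num:07d}", label=label,
                         synonyms=tuple(synonyms), obsolete=obsolete))
    path = tmp_path_factory.mktemp("tbl") / "o.tbl"
    write_tbl(onto, path)
    assert parse_tbl(path, namespace="Z") == onto


def test_parse_gold_tsv_and_merge(tmp_path):
    path = tmp_path / "gold.tsv"
    path.write_text(
        "phenotype_id\tentity_ids\tquality_ids\n"
        "MP:0004650\tMA:0000312\tPATO:0002001\n"
        "MP:0000002\tMA:0000001\tPATO:0000001\n"
        "MP:0004650\tMA:0000999\tPATO:0000462\n",
        encoding="utf-8",
    )
    gold = parse_gold_eq(path)
    assert len(gold) == 2  # duplicate phenotype rows merged by set union
    merged = {g.phenotype_id: g for g in gold}["MP:0004650"]
    assert merged.entity_ids == {"MA:0000312", "MA:0000999"}
    assert merged.quality_ids == {"PATO:0002001", "PATO:0000462"}


def test_parse_gold_empty_file(tmp_path):
    path = tmp_path / "gold.tsv"
    path.write_text("phenotype_id\tentity_ids\tquality_ids\n", encoding="utf-8")
    assert parse_gold_eq(path) == []


def test_parse_gold_missing_quality_rejected(tmp_path):
    path = tmp_path / "gold.tsv"
    path.write_text("phenotype_id\tentity_ids\tquality_ids\nMP:1\tMA:1\t\n",
                    encoding="utf-8")
    with pytest.raises(ValueError, match="quality"):
        parse_gold_eq(path)


def test_parse_gold_obo_logical_definitions(tmp_path):
    path = tmp_path / "gold.obo"
    path.write_text(
        "format-version: 1.2\n\n[Term]\nid: MP:0004650\n"
        "intersection_of: PATO:0002001\n"
        "intersection_of: inheres_in MA:0000312 ! lumbar vertebra\n",
        encoding="utf-8",
    )
    (gold,) = parse_gold_eq(path)
    assert gold == GoldEQ("MP:0004650", frozenset({"MA:0000312"}),
                          frozenset({"PATO:0002001"}))


def test_select_structure_process():
    gold = [
        GoldEQ("MP:1", frozenset({"MA:1"}), frozenset({"PATO:1"})),
        GoldEQ("MP:2", frozenset({"CHEBI:1"}), frozenset({"PATO:1"})),
        GoldEQ("MP:3", frozenset({"GO:1", "MA:2"}), frozenset({"PATO:2"})),
        GoldEQ("MP:4", frozenset({"MA:1"}), frozenset({"BFO:1"})),
    ]
    kept = select_structure_process(gold, {"MA"}, {"GO"}, "PATO")
    assert [g.phenotype_id for g in kept] == ["MP:1", "MP:3"]
    # subset of input and idempotent
    assert select_structure_process(kept, {"MA"}, {"GO"}, "PATO") == kept
    for g in kept:
        assert all(is_curie(i) for i in g.entity_ids | g.quality_ids)


def test_select_structure_process_rejects_overlapping_namespaces():
    with pytest.raises(ValueError):
        select_structure_process([], {"MA"}, {"MA"}, "PATO")
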