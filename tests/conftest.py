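import pytest

from phenoeq.ontology import Concept, Ontology


@pytest.fixture
def pato_trio() -> Ontology:
    """Quality ontology with one composite ('decreased depth') and its two
    components."""
    onto = Ontology("PATO")
    onto.add(Concept(id="PATO:0001472", label="decreased depth"))
    onto.add(Concept(id="PATO:0001997", label="decreased"))
    onto.add(Concept(id="PATO:0001595", label="depth"))
    return onto


@pytest.fixture
def anatomy_small() -> Ontology:
    onto = Ontology("MA")
    onto.add(Concept(id="MA:0000232", label="dorsal root ganglion"))
    onto.add(Concept(id="MA:0000312", label="lumbar vertebra"))
    return onto


@pytest.fixture
def quality_small() -> Ontology:
    onto = Ontology("PATO")
    onto.add(Concept(id="PATO:0001233", label="dorsal"))
    onto.add(Concept(id="PATO:0000600", label="enlarged", synonyms=("big",)))
    onto.add(Concept(id="PATO:0000462", label="absent"))
    onto.add(Concept(id="PATO:0002000", label="lacks all parts of type"))
    onto.add(Concept(id="PATO:0000470", label="increased"))
    onto.add(Concept(id="PATO:0000912", label="increased rate"))
    onto.add(Concept(id="PATO:0002001", label="has extra parts of type"))
    return onto
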