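import pytest

from cytotext import corpus_model as cm
from cytotext import synthetic_data as sd


@pytest.fixture
def chain_ontology():
    """root -> A -> B."""
    terms = {t: cm.OntologyTerm(t, label=t.lower()) for t in ("ROOT", "A", "B")}
    return cm.Ontology(terms, [("A", "ROOT"), ("B", "A")], root_id="ROOT")


@pytest.fixture
def diamond_ontology():
    """root->A->C, root->B->C, plus a direct root->C edge."""
    terms = {t: cm.OntologyTerm(t, label=t.lower()) for t in ("ROOT", "A", "B", "C")}
    edges = [("A", "ROOT"), ("B", "ROOT"), ("C", "A"), ("C", "B"), ("C", "ROOT")]
    return cm.Ontology(terms, edges, root_id="ROOT")


@pytest.fixture
def toy_passage():
    text = "We observed exhausted CD8+ T cells and neuron subtypes here."
    return cm.Passage(doc_id="D1", passage_type="paragraph", text=text,
                      year=2021, journal="Toy Biol")


@pytest.fixture
def small_corpus():
    config = sd.GeneratorConfig(seed=11, n_passages=40, multi_id_fraction=0.1)
    corpus, truth = sd.generate_corpus(config)
    return corpus, truth


@pytest.fixture
def small_ontology():
    return sd.generate_ontology(4, 3, 2, seed=11,
                                lineage_labels=sd.DEFAULT_LINEAGES)
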