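import pytest

from ickg import (
    GazetteerTagger,
    VerbLookupBackend,
    build_graph_from_corpus,
    generate_planted_reasoning_graph,
    generate_synthetic_corpus,
)


@pytest.fixture(scope="session")
def synthetic_corpus():
    """Small planted corpus shared by pipeline-level tests."""
    return generate_synthetic_corpus(
        n_genes=12, n_pathways=4, n_relations=10, abstracts_per_relation=3, seed=101
    )


@pytest.fixture(scope="session")
def assembled(synthetic_corpus):
    records, truth = synthetic_corpus
    tagger = GazetteerTagger(truth.gazetteer())
    graph, triples, log = build_graph_from_corpus(records, tagger, VerbLookupBackend())
    return graph, triples, log, truth


@pytest.fixture(scope="session")
def planted_reasoning():
    return generate_planted_reasoning_graph(seed=13)
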