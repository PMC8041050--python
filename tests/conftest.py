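import pytest

from diagtutor.embeddings import train_embeddings
from diagtutor.ontology import Concept, Ontology
from diagtutor.siamese import LabeledPair, SiameseMatcher
from diagtutor.synthetic import make_paraphrase_benchmark, table1_case, table1_ontology


@pytest.fixture(scope="session")
def chain_ontology():
    """12 concepts in a single is-a chain; each label carries a unique token."""
    return Ontology(
        Concept(
            f"N{i:02d}",
            f"chain disease {i:02d}",
            (),
            () if i == 0 else (f"N{i - 1:02d}",),
        )
        for i in range(12)
    )


@pytest.fixture(scope="session")
def resp_ontology():
    return table1_ontology()


@pytest.fixture()
def worked_case():
    return table1_case()


@pytest.fixture(scope="session")
def tiny_matcher():
    """A small matcher overfit on four separable pairs (fast, deterministic)."""
    corpus = [
        "do you have a fever",
        "are you feverish",
        "do you have a sore throat",
        "is your throat sore",
        "do you feel hot",
    ]
    emb = train_embeddings(corpus, [("fever", "feverish")], dimension=16, seed=0)
    matcher = SiameseMatcher(emb, hidden_size=20, max_len=30, seed=0)
    pairs = [
        LabeledPair("do you have a fever", "are you feverish", 1),
        LabeledPair("do you have a sore throat", "is your throat sore", 1),
        LabeledPair("do you have a fever", "is your throat sore", 0),
        LabeledPair("do you have a sore throat", "do you feel hot", 0),
    ]
    matcher.train(pairs, epochs=200, learning_rate=0.05, seed=0)
    return matcher


@pytest.fixture(scope="session")
def benchmark():
    return make_paraphrase_benchmark(seed=42)


@pytest.fixture(scope="session")
def trained_benchmark_matcher(benchmark):
    """Embeddings + Siamese matcher trained once on the benchmark pairs."""
    emb = train_embeddings(
        list(benchmark.corpus), list(benchmark.synonym_pairs), dimension=32, seed=1
    )
    matcher = SiameseMatcher(emb, hidden_size=50, max_len=30, seed=1)
    matcher.train(list(benchmark.train_pairs), epochs=40, learning_rate=0.02, seed=1)
    return matcher
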