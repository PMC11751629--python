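import numpy as np
import pytest

from txscout import (
    Corpus,
    GeneratorConfig,
    SampleRecord,
    SearchIndex,
    StudyRecord,
    generate_corpus,
)


@pytest.fixture(scope="session")
def tiny_corpus() -> Corpus:
    """Hand-built 3-study corpus with known counts for exact assertions."""
    genes = ["g1", "g2", "g3", "g4"]
    studies = [
        StudyRecord("ST1", "heart muscle study", "cardiac tissue profiling", "2 conditions"),
        StudyRecord("ST2", "brain cortex study", "neuronal expression atlas", ""),
        StudyRecord("ST3", "", "", ""),
    ]
    samples = [
        SampleRecord("SM1", "ST1", "treated", "heart sample one", "heart"),
        SampleRecord("SM2", "ST1", "treated", "heart sample two", "heart"),
        SampleRecord("SM3", "ST1", "control", "heart control", "heart"),
        SampleRecord("SM4", "ST2", "", "brain sample", "cortex"),
        SampleRecord("SM5", "ST3", "", "", ""),
    ]
    counts = np.array(
        [
            [1, 3, 5, 7, 0],
            [3, 5, 2, 1, 0],
            [0, 0, 9, 4, 2],
            [2, 2, 2, 2, 2],
        ]
    )
    return Corpus(counts=counts, gene_ids=genes, samples=samples, studies=studies)


@pytest.fixture(scope="session")
def planted():
    """Default planted-topic corpus: 5 topics x 12 studies x 4 samples, 500 genes."""
    config = GeneratorConfig(seed=1)
    corpus, truth, topics = generate_corpus(config)
    return corpus, truth, topics


@pytest.fixture(scope="session")
def planted_index(planted) -> SearchIndex:
    corpus, _, _ = planted
    with pytest.warns(UserWarning, match="does not reduce dimension"):
        return SearchIndex.build(corpus)


@pytest.fixture(scope="session")
def small_index(planted):
    """Index with k=200 < n_genes so no dimensionality warning fires."""
    corpus, _, _ = planted
    return SearchIndex.build(corpus, k=200, jl_seed=0)
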