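"""Seeded generator of ARCHS4-style corpora with planted topic structure.

Studies are grouped into latent topics. Each topic owns a vocabulary of
pseudo-biomedical terms (disjoint across topics by default; a configurable
overlap fraction shares terms to make retrieval harder) and an upregulated
gene signature. Study text is built from sentence templates filled with topic
vocabulary, so a text query drawn from a topic's vocabulary should rank that
topic's studies first. Counts are negative-binomial (overdispersed, matching
RNA-seq count structure); in each study, the signature genes of its topic are
fold-changed in one designated condition (with the default single condition
per study, that is the whole study). Every draw is fixed by the config seed.

The generator emulates the corpus shape the retrieval pipeline ingests:
grouped studies, per-sample and per-study text, and a count matrix written in
the same HDF5 layout the reader expects. Truth labels (study -> topic) make
every pipeline stage testable without downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import (
    Corpus,
    GeneSet,
    H5Layout,
    ARCHS4_V2_LAYOUT,
    SampleRecord,
    StudyRecord,
    write_corpus,
)

__all__ = [
    "GeneratorConfig",
    "TopicSpec",
    "generate_corpus",
    "make_query",
    "write_fixture",
    "write_truth_tsv",
]

_PREFIXES = [
    "cardio", "neuro", "hepato", "immuno", "dermato", "osteo", "nephro",
    "pulmo", "hemato", "gastro", "thymo", "angio", "myelo", "adipo",
    "chondro", "fibro", "glio", "kerato", "lympho", "melano",
]
_SUFFIXES = [
    "myocyte", "genesis", "blast", "fibrosis", "regeneration", "signaling",
    "differentiation", "inflammation", "proliferation", "senescence",
    "apoptosis", "hypoxia", "stimulation", "activation", "remodeling",
    "infection", "toxicity", "maturation", "plasticity", "metabolism",
]

_STUDY_TITLE_TEMPLATES = [
    "Transcriptional profiling of {0} and {1} in human samples",
    "RNA-seq analysis of {0} during {1}",
    "Gene expression changes in {0} following {1}",
    "Expression landscape of {0}, {1} and {2}",
]
_QUERY_TEMPLATES = [
    "studies of {0} and {1} involving {2} with {3} or {4} and {5}",
    "experiments on {0} {1} {2} measuring {3} {4} {5}",
    "datasets about {0}, {1}, {2}, {3}, {4} and {5}",
]

_N_QUERY_WORDS = 6


@dataclass(frozen=True)
class TopicSpec:
    """A latent topic: its vocabulary, gene signature and text templates."""

    topic_id: str
    vocabulary: tuple[str, ...]
    signature_genes: frozenset[str]
    fold_change: float
    metadata_templates: tuple[str, ...] = tuple(_STUDY_TITLE_TEMPLATES)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic corpus; the seed fixes every random draw.

    Defaults describe a desk-scale corpus: 5 topics x 12 studies x 4 samples
    (240 samples), 500 genes, 20-gene signatures at 4-fold upregulation over
    a negative-binomial baseline (mean 50, dispersion 0.3).
    """

    n_topics: int = 5
    studies_per_topic: int = 12
    samples_per_study: int = 4
    conditions_per_study: int = 1
    n_genes: int = 500
    signature_size: int = 20
    fold_change: float = 4.0
    nb_dispersion: float = 0.3
    baseline_mean: float = 50.0
    vocab_size: int = 24
    vocab_overlap: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        positive = {
            "n_topics": self.n_topics,
            "studies_per_topic": self.studies_per_topic,
            "samples_per_study": self.samples_per_study,
            "conditions_per_study": self.conditions_per_study,
            "n_genes": self.n_genes,
            "signature_size": self.signature_size,
            "fold_change": self.fold_change,
            "baseline_mean": self.baseline_mean,
            "vocab_size": self.vocab_size,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if not 0.0 <= self.vocab_overlap <= 1.0:
            raise ValueError("vocab_overlap must be in [0, 1]")
        if self.signature_size > self.n_genes:
            raise ValueError(
                f"signature_size {self.signature_size} exceeds n_genes {self.n_genes}"
            )
        if self.signature_size * self.n_topics > self.n_genes:
            raise ValueError("topic signatures do not fit disjointly in the gene universe")


def _word_pool(rng: np.random.Generator) -> list[str]:
    words = [p + s for p in _PREFIXES for s in _SUFFIXES]
    rng.shuffle(words)
    return words


def _topic_vocabularies(config: GeneratorConfig, rng: np.random.Generator) -> list[tuple[str, ...]]:
    pool = _word_pool(rng)
    n_shared = int(round(config.vocab_size * config.vocab_overlap))
    n_own = config.vocab_size - n_shared
    needed = n_shared + n_own * config.n_topics
    if needed > len(pool):
        raise ValueError(
            f"vocabulary pool exhausted: need {needed} words, have {len(pool)}"
        )
    shared = pool[:n_shared]
    vocabularies = []
    cursor = n_shared
    for _ in range(config.n_topics):
        own = pool[cursor : cursor + n_own]
        cursor += n_own
        vocabularies.append(tuple(own + shared))
    return vocabularies


def _fill(template: str, words: Sequence[str]) -> str:
    slots = template.count("{")
    return template.format(*(list(words) * slots)[:slots])


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[Corpus, dict[str, str], list[TopicSpec]]:
    """Generate a planted-topic corpus.

    Returns the corpus, truth labels (study_id -> topic_id), and the topic
    specs (vocabulary + signature) used to plant it.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    gene_perm = rng.permutation(config.n_genes)
    vocabularies = _topic_vocabularies(config, rng)

    topics: list[TopicSpec] = []
    for t in range(config.n_topics):
        sig_idx = gene_perm[t * config.signature_size : (t + 1) * config.signature_size]
        topics.append(
            TopicSpec(
                topic_id=f"topic{t}",
                vocabulary=vocabularies[t],
                signature_genes=frozenset(gene_ids[i] for i in sig_idx),
                fold_change=config.fold_change,
            )
        )

    sig_index = {
        topic.topic_id: np.array(
            [i for i, g in enumerate(gene_ids) if g in topic.signature_genes]
        )
        for topic in topics
    }

    studies: list[StudyRecord] = []
    samples: list[SampleRecord] = []
    truth: dict[str, str] = {}
    mu_columns: list[np.ndarray] = []

    study_no = 0
    for topic in topics:
        for _ in range(config.studies_per_topic):
            study_id = f"SYN{study_no:05d}"
            study_no += 1
            truth[study_id] = topic.topic_id

            title = _fill(
                topic.metadata_templates[rng.integers(len(topic.metadata_templates))],
                rng.choice(topic.vocabulary, size=3, replace=False),
            )
            # The summary enumerates the topic vocabulary (shuffled) so every
            # study expresses its topic's terms fully: topics stay separable
            # by construction, the point of disjoint vocabularies.
            summary_words = rng.permutation(np.asarray(topic.vocabulary))
            summary = "This study examines " + ", ".join(summary_words) + " in human samples."
            design = (
                f"{config.samples_per_study} samples across "
                f"{config.conditions_per_study} condition(s); RNA-seq counts."
            )
            studies.append(StudyRecord(study_id, title, summary, design))

            for j in range(config.samples_per_study):
                condition = j % config.conditions_per_study
                sample_id = f"{study_id}S{j:03d}"
                samples.append(
                    SampleRecord(
                        sample_id=sample_id,
                        study_id=study_id,
                        condition_label=f"cond{condition}",
                        sample_text=f"{study_id} replicate {j} cond{condition}",
                        source_name=f"{summary_words[0]} tissue",
                    )
                )
                mu = np.full(config.n_genes, config.baseline_mean, dtype=np.float64)
                # condition 0 carries the topic signature
                if condition == 0:
                    mu[sig_index[topic.topic_id]] *= config.fold_change
                mu_columns.append(mu)

    mu_matrix = np.column_stack(mu_columns)
    if config.nb_dispersion > 0:
        r = 1.0 / config.nb_dispersion
        p = r / (r + mu_matrix)
        counts = rng.negative_binomial(r, p)
    else:
        counts = rng.poisson(mu_matrix)

    corpus = Corpus(
        counts=counts.astype(np.int64),
        gene_ids=gene_ids,
        samples=samples,
        studies=studies,
    )
    return corpus, truth, topics


def make_query(topic: TopicSpec, seed: int = 0) -> tuple[str, GeneSet]:
    """Build a (query text, gene set) pair for a topic, deterministic per seed.

    The text fills a query template with topic vocabulary; the gene set is
    the topic's planted signature, described by the text — mirroring curated
    gene sets that carry a textual description of their source experiment.
    """
    rng = np.random.default_rng(seed)
    template = _QUERY_TEMPLATES[int(rng.integers(len(_QUERY_TEMPLATES)))]
    words = rng.choice(
        topic.vocabulary, size=min(_N_QUERY_WORDS, len(topic.vocabulary)), replace=False
    )
    text = _fill(template, words)
    gene_set = GeneSet(
        name=f"{topic.topic_id}_signature",
        description=text,
        genes=topic.signature_genes,
    )
    return text, gene_set


def write_fixture(
    corpus: Corpus, path: str | Path, layout: H5Layout = ARCHS4_V2_LAYOUT
) -> Path:
    """Write a generated corpus as an HDF5 fixture readable by the corpus reader."""
    return write_corpus(corpus, path, layout)


def write_truth_tsv(truth: dict[str, str], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("study_id\ttopic_id\n")
        for study_id, topic_id in truth.items():
            fh.write(f"{study_id}\t{topic_id}\n")
    return path


def config_to_dict(config: GeneratorConfig) -> dict:
    return asdict(config)
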