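"""Transcriptome embedding: condition aggregation and Johnson-Lindenstrauss projection.

Counts are first averaged within each (study, experimental condition) group to
give one mean-count profile per condition, then projected to ``k`` dimensions
(default 1000) with a dense Gaussian random projection whose matrix is fully
determined by ``(n_genes, k, seed)``. By the Johnson-Lindenstrauss lemma the
projection approximately preserves pairwise Euclidean distances, so cosine
nearest-neighbour search in the projected space tracks similarity between
full-length profiles.

The default preprocessing is the raw mean-count profile; ``log1p_cpm``
(counts-per-million then log1p) is offered for scale robustness. Gene-set
queries enter this space as 0/1 indicator pseudo-profiles over the corpus
gene universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .corpus import Corpus, EmbeddingDB, GeneSet, SampleRecord

__all__ = [
    "CONDITION_SEP",
    "ConditionProfile",
    "DEFAULT_JL_DIM",
    "EmptyQueryProfileError",
    "JLProjector",
    "aggregate_conditions",
    "condition_id",
    "default_condition_key",
    "fit_jl_projector",
    "geneset_to_pseudoprofile",
    "project",
    "project_vector",
    "split_condition_id",
]

DEFAULT_JL_DIM = 1000

#: Separator between study id and condition label in TranscriptomeDB keys.
#: A tab cannot occur inside an accession or condition label and is JSON-safe.
CONDITION_SEP = "\t"


class EmptyQueryProfileError(ValueError):
    """Raised when a gene-set query shares no genes with the corpus universe."""


@dataclass(frozen=True)
class ConditionProfile:
    """Mean count vector of one experimental condition within a study."""

    study_id: str
    condition_label: str
    mean_counts: np.ndarray = field(repr=False)

    @property
    def key(self) -> str:
        return condition_id(self.study_id, self.condition_label)


def condition_id(study_id: str, condition_label: str) -> str:
    return f"{study_id}{CONDITION_SEP}{condition_label}"


def split_condition_id(key: str) -> tuple[str, str]:
    study_id, _, condition_label = key.partition(CONDITION_SEP)
    return study_id, condition_label


def default_condition_key(sample: SampleRecord) -> str:
    """Condition label if set, else source name, else the sample's own id.

    A sample with no usable grouping field becomes its own singleton
    condition rather than being merged with unrelated samples.
    """
    return sample.condition_label or sample.source_name or sample.sample_id


def aggregate_conditions(
    corpus: Corpus,
    condition_key: Callable[[SampleRecord], str] = default_condition_key,
) -> list[ConditionProfile]:
    """Average count columns within each (study, condition) group.

    Profiles are returned ordered by (study_id, condition_label). Studies with
    no samples are skipped with a warning.
    """
    groups: dict[tuple[str, str], list[int]] = {}
    for i, sample in enumerate(corpus.samples):
        groups.setdefault((sample.study_id, condition_key(sample)), []).append(i)

    populated = {study for study, _ in groups}
    empty = [s.study_id for s in corpus.studies if s.study_id not in populated]
    if empty:
        warnings.warn(
            f"{len(empty)} study(ies) with no samples skipped: {empty[:5]}",
            stacklevel=2,
        )

    counts = np.asarray(corpus.counts, dtype=np.float64)
    profiles = [
        ConditionProfile(study, label, counts[:, cols].mean(axis=1))
        for (study, label), cols in groups.items()
    ]
    profiles.sort(key=lambda p: (p.study_id, p.condition_label))
    return profiles


@dataclass(frozen=True)
class JLProjector:
    """Seeded dense Gaussian random projection, entries scaled by 1/sqrt(k)."""

    n_genes: int
    k: int
    seed: int
    matrix: np.ndarray = field(repr=False)

    @classmethod
    def fit(cls, n_genes: int, k: int = DEFAULT_JL_DIM, seed: int = 0) -> "JLProjector":
        if n_genes < 1:
            raise ValueError(f"n_genes must be >= 1, got {n_genes}")
        if k < 1:
            raise ValueError(f"k must be >= 1, got {k}")
        if k > n_genes:
            warnings.warn(
                f"k={k} exceeds n_genes={n_genes}: projection does not reduce dimension",
                stacklevel=2,
            )
        rng = np.random.default_rng(seed)
        matrix = rng.standard_normal((k, n_genes)) / np.sqrt(k)
        return cls(n_genes=n_genes, k=k, seed=seed, matrix=matrix)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.matrix @ np.asarray(x, dtype=np.float64)


def fit_jl_projector(n_genes: int, k: int = DEFAULT_JL_DIM, seed: int = 0) -> JLProjector:
    """Functional alias for :meth:`JLProjector.fit`."""
    return JLProjector.fit(n_genes, k, seed)


def _log1p_cpm(x: np.ndarray) -> np.ndarray:
    total = x.sum()
    if total <= 0:
        return np.zeros_like(x)
    return np.log1p(x / total * 1e6)


_PREPROCESS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "raw_mean": lambda x: x,
    "log1p_cpm": _log1p_cpm,
}


def _preprocess_fn(name: str) -> Callable[[np.ndarray], np.ndarray]:
    try:
        return _PREPROCESS[name]
    except KeyError:
        raise ValueError(
            f"unknown preprocess {name!r}; available: {sorted(_PREPROCESS)}"
        ) from None


def project(
    profiles: Sequence[ConditionProfile],
    projector: JLProjector,
    preprocess: str = "raw_mean",
) -> EmbeddingDB:
    """Project condition profiles into JL space, one row per profile.

    Under ``raw_mean`` the map is linear in the input profile.
    """
    fn = _preprocess_fn(preprocess)
    rows = []
    for p in profiles:
        if p.mean_counts.shape[0] != projector.n_genes:
            raise ValueError(
                f"profile {p.key!r} has {p.mean_counts.shape[0]} genes, "
                f"projector expects {projector.n_genes}"
            )
        rows.append(projector(fn(p.mean_counts)))
    vectors = np.vstack(rows) if rows else np.zeros((0, projector.k))
    return EmbeddingDB(
        ids=[p.key for p in profiles],
        vectors=vectors,
        meta={
            "kind": "transcriptome",
            "n_genes": int(projector.n_genes),
            "k": int(projector.k),
            "seed": int(projector.seed),
            "preprocess": preprocess,
        },
    )


def project_vector(
    vec: np.ndarray, projector: JLProjector, preprocess: str = "raw_mean"
) -> np.ndarray:
    """Project a single gene-space vector (e.g. a query pseudo-profile)."""
    vec = np.asarray(vec, dtype=np.float64)
    if vec.shape[0] != projector.n_genes:
        raise ValueError(
            f"vector has {vec.shape[0]} genes, projector expects {projector.n_genes}"
        )
    return projector(_preprocess_fn(preprocess)(vec))


def geneset_to_pseudoprofile(gene_set: GeneSet, gene_ids: Sequence[str]) -> np.ndarray:
    """0/1 indicator vector of the gene set over the corpus gene universe."""
    members = gene_set.genes
    vec = np.fromiter((1.0 if g in members else 0.0 for g in gene_ids), dtype=np.float64)
    if vec.sum() == 0:
        raise EmptyQueryProfileError(
            f"gene set {gene_set.name!r} shares no genes with the corpus universe"
        )
    return vec
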