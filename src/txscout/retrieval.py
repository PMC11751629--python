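"""Two-stage retrieval: cosine kNN over metadata and transcriptome databases.

Stage 1 ranks studies directly against the query (semantic text search, or
transcriptome search seeded by a gene-set pseudo-profile). Stage 2 expands the
stage-1 studies by using each one's own embedding as a new query against
either database. Six strategies cover every stage combination; the default is
semantic search followed by transcriptome expansion.

All search is exhaustive scan with exact cosine scores; ties break by
lexicographic id so results are reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import Corpus, EmbeddingDB, GeneSet
from .embed_text import HashingTextEmbedder, TextEmbedder, build_metadata_db, embed_query
from .embed_tx import (
    DEFAULT_JL_DIM,
    JLProjector,
    aggregate_conditions,
    geneset_to_pseudoprofile,
    project,
    project_vector,
    split_condition_id,
)

__all__ = [
    "DegenerateQueryError",
    "EmptyDatabaseError",
    "Hit",
    "QueryResult",
    "SearchIndex",
    "StrategyId",
    "StrategyQueryError",
    "expand",
    "knn_cosine",
    "run_strategy",
    "search_semantic",
    "search_transcriptome",
]


class DegenerateQueryError(ValueError):
    """Raised when a query embeds to the zero vector."""


class EmptyDatabaseError(ValueError):
    """Raised when searching an embedding database with no entries."""


class StrategyQueryError(ValueError):
    """Raised when the query type does not match the strategy's first stage."""


class StrategyId(str, Enum):
    """Retrieval sequences: stage-1 search space + stage-2 expansion space.

    S = semantic (metadata text), T = transcriptome. ``S_PLUS_T`` is the
    default: semantic search first, then transcriptome expansion.
    """

    S_ONLY = "s"
    T_ONLY = "t"
    S_PLUS_T = "s+t"
    T_PLUS_S = "t+s"
    S_PLUS_S = "s+s"
    T_PLUS_T = "t+t"


DEFAULT_STRATEGY = StrategyId.S_PLUS_T

_SEMANTIC_FIRST = {StrategyId.S_ONLY, StrategyId.S_PLUS_T, StrategyId.S_PLUS_S}
_EXPANSION_MODE = {
    StrategyId.S_PLUS_T: "transcriptome",
    StrategyId.T_PLUS_S: "semantic",
    StrategyId.S_PLUS_S: "semantic",
    StrategyId.T_PLUS_T: "transcriptome",
}


@dataclass(frozen=True)
class Hit:
    """One retrieved study with its cosine score and, for stage 2, its seed."""

    study_id: str
    score: float
    seed_study: str | None = None


def knn_cosine(
    query_vec: np.ndarray, db: EmbeddingDB, n: int
) -> list[tuple[str, float]]:
    """Top-``n`` database entries by cosine similarity to ``query_vec``.

    Exhaustive scan; descending score, ties broken by lexicographic id.
    ``n`` larger than the database returns everything. All-zero database rows
    score 0 against any query.
    """
    if len(db) == 0:
        raise EmptyDatabaseError("cannot search an empty embedding database")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    q = np.asarray(query_vec, dtype=np.float64)
    qnorm = np.linalg.norm(q)
    if qnorm == 0:
        raise DegenerateQueryError("degenerate query: zero embedding vector")
    row_norms = np.linalg.norm(db.vectors, axis=1)
    safe = np.where(row_norms > 0, row_norms, 1.0)
    scores = (db.vectors @ q) / (safe * qnorm)
    scores = np.where(row_norms > 0, scores, 0.0)
    scores = np.clip(scores, -1.0, 1.0)
    order = np.lexsort((np.asarray(db.ids, dtype=object), -scores))
    top = order[: min(n, len(db))]
    return [(db.ids[i], float(scores[i])) for i in top]


def _collapse_to_studies(pairs: Sequence[tuple[str, float]]) -> list[tuple[str, float]]:
    """Collapse (condition-key, score) pairs to per-study best score."""
    best: dict[str, float] = {}
    for key, score in pairs:
        study, _ = split_condition_id(key)
        if study not in best or score > best[study]:
            best[study] = score
    return sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))


def search_semantic(
    query_text: str,
    metadata_db: EmbeddingDB,
    embedder: TextEmbedder,
    n_search: int,
) -> list[Hit]:
    """Stage-1 natural-language search over the study metadata database."""
    qvec = embed_query(query_text, embedder)
    return [Hit(sid, score) for sid, score in knn_cosine(qvec, metadata_db, n_search)]


def search_transcriptome(
    gene_set: GeneSet,
    transcriptome_db: EmbeddingDB,
    projector: JLProjector,
    gene_ids: Sequence[str],
    n_search: int,
    preprocess: str = "raw_mean",
) -> list[Hit]:
    """Stage-1 gene-set search over the transcriptome database.

    The gene set becomes an indicator pseudo-profile, is projected like any
    condition profile, and condition hits are collapsed to studies keeping
    each study's best score.
    """
    pseudo = geneset_to_pseudoprofile(gene_set, gene_ids)
    qvec = project_vector(pseudo, projector, preprocess)
    scored = knn_cosine(qvec, transcriptome_db, len(transcriptome_db))
    studies = _collapse_to_studies(scored)
    return [Hit(sid, score) for sid, score in studies[:n_search]]


@dataclass
class SearchIndex:
    """Everything needed to execute any strategy against one corpus."""

    embedder: TextEmbedder
    metadata_db: EmbeddingDB
    transcriptome_db: EmbeddingDB
    projector: JLProjector
    gene_ids: list[str]
    preprocess: str
    study_samples: dict[str, list[str]]

    @classmethod
    def build(
        cls,
        corpus: Corpus,
        embedder: TextEmbedder | None = None,
        k: int = DEFAULT_JL_DIM,
        jl_seed: int = 0,
        preprocess: str = "raw_mean",
    ) -> "SearchIndex":
        """Build both embedding databases from a corpus in one pass."""
        if embedder is None:
            embedder = HashingTextEmbedder()
        metadata_db = build_metadata_db(corpus, embedder)
        profiles = aggregate_conditions(corpus)
        projector = JLProjector.fit(corpus.n_genes, k=k, seed=jl_seed)
        transcriptome_db = project(profiles, projector, preprocess)
        return cls(
            embedder=embedder,
            metadata_db=metadata_db,
            transcriptome_db=transcriptome_db,
            projector=projector,
            gene_ids=list(corpus.gene_ids),
            preprocess=preprocess,
            study_samples=corpus.study_sample_ids(),
        )

    def transcriptome_rows_of(self, study_id: str) -> np.ndarray:
        idx = [
            i
            for i, key in enumerate(self.transcriptome_db.ids)
            if split_condition_id(key)[0] == study_id
        ]
        return self.transcriptome_db.vectors[idx]


def expand(
    hits: Sequence[Hit],
    mode: str,
    index: SearchIndex,
    n_expand: int,
) -> list[Hit]:
    """Stage-2 expansion: each stage-1 study's own embedding becomes a query.

    ``mode`` selects the target space (``semantic`` or ``transcriptome``).
    Each seed contributes its top ``n_expand`` neighbours (the seed study is
    excluded from its own list); the union keeps each retrieved study's best
    (score, seed) pair, ranked by score then id.
    """
    if mode not in {"semantic", "transcriptome"}:
        raise ValueError(f"unknown expansion mode {mode!r}")
    if n_expand == 0 or not hits:
        return []
    best: dict[str, Hit] = {}
    for seed in hits:
        if mode == "semantic":
            if seed.study_id not in index.metadata_db:
                warnings.warn(
                    f"seed study {seed.study_id} absent from metadata DB; skipped",
                    stacklevel=2,
                )
                continue
            seed_vecs = index.metadata_db.vector_for(seed.study_id)[None, :]
            target_db = index.metadata_db
            collapse = False
        else:
            seed_vecs = index.transcriptome_rows_of(seed.study_id)
            if seed_vecs.shape[0] == 0:
                warnings.warn(
                    f"seed study {seed.study_id} absent from transcriptome DB; skipped",
                    stacklevel=2,
                )
                continue
            target_db = index.transcriptome_db
            collapse = True

        # Best score per candidate study over all of the seed's vectors.
        per_seed: dict[str, float] = {}
        for vec in seed_vecs:
            if np.linalg.norm(vec) == 0:
                continue
            scored = knn_cosine(vec, target_db, len(target_db))
            pairs = _collapse_to_studies(scored) if collapse else scored
            for study, score in pairs:
                if study == seed.study_id:
                    continue
                if study not in per_seed or score > per_seed[study]:
                    per_seed[study] = score
        ranked = sorted(per_seed.items(), key=lambda kv: (-kv[1], kv[0]))[:n_expand]
        for study, score in ranked:
            if study not in best or score > best[study].score:
                best[study] = Hit(study, score, seed_study=seed.study_id)
    return sorted(best.values(), key=lambda h: (-h.score, h.study_id))


@dataclass
class QueryResult:
    """Ranked retrieval output with per-stage provenance."""

    strategy: StrategyId
    query_text: str | None
    gene_set_name: str | None
    n_search: int
    n_expand: int
    stage1: list[Hit]
    stage2: list[Hit]
    studies: list[str] = field(default_factory=list)
    samples: list[str] = field(default_factory=list)

    def top_studies(self, k: int) -> list[str]:
        """First ``k`` studies: stage-1 in rank order, then stage-2 by score."""
        return self.studies[:k]

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy.value,
            "query_text": self.query_text,
            "gene_set_name": self.gene_set_name,
            "params": {"n_search": self.n_search, "n_expand": self.n_expand},
            "stage1_hits": [
                {"study_id": h.study_id, "score": h.score} for h in self.stage1
            ],
            "stage2_hits": [
                {"study_id": h.study_id, "score": h.score, "seed_study": h.seed_study}
                for h in self.stage2
            ],
            "studies": self.studies,
            "samples": self.samples,
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "QueryResult":
        d = json.loads(Path(path).read_text())
        return cls(
            strategy=StrategyId(d["strategy"]),
            query_text=d["query_text"],
            gene_set_name=d["gene_set_name"],
            n_search=d["params"]["n_search"],
            n_expand=d["params"]["n_expand"],
            stage1=[Hit(h["study_id"], h["score"]) for h in d["stage1_hits"]],
            stage2=[
                Hit(h["study_id"], h["score"], h["seed_study"])
                for h in d["stage2_hits"]
            ],
            studies=list(d["studies"]),
            samples=list(d["samples"]),
        )


def run_strategy(
    strategy: StrategyId | str,
    index: SearchIndex,
    query_text: str | None = None,
    gene_set: GeneSet | None = None,
    n_search: int = 10,
    n_expand: int = 10,
) -> QueryResult:
    """Execute one retrieval sequence end to end.

    Semantic-first strategies require ``query_text``; transcriptome-first
    strategies require ``gene_set``. The returned studies are the
    deduplicated stage-1 hits (rank order) followed by stage-2 hits (score
    order); samples are all corpus samples of those studies.
    """
    strategy = StrategyId(strategy)
    if strategy in _SEMANTIC_FIRST:
        if query_text is None:
            raise StrategyQueryError(f"strategy {strategy.value} requires a text query")
        stage1 = search_semantic(query_text, index.metadata_db, index.embedder, n_search)
    else:
        if gene_set is None:
            raise StrategyQueryError(
                f"strategy {strategy.value} requires a gene-set query"
            )
        stage1 = search_transcriptome(
            gene_set,
            index.transcriptome_db,
            index.projector,
            index.gene_ids,
            n_search,
            index.preprocess,
        )

    mode = _EXPANSION_MODE.get(strategy)
    stage2 = expand(stage1, mode, index, n_expand) if mode else []

    studies: list[str] = []
    seen: set[str] = set()
    for h in [*stage1, *stage2]:
        if h.study_id not in seen:
            seen.add(h.study_id)
            studies.append(h.study_id)
    samples = [sid for study in studies for sid in index.study_samples.get(study, [])]

    return QueryResult(
        strategy=strategy,
        query_text=query_text,
        gene_set_name=gene_set.name if gene_set is not None else None,
        n_search=n_search,
        n_expand=n_expand,
        stage1=stage1,
        stage2=stage2,
        studies=studies,
        samples=samples,
    )
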