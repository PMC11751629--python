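"""Retrieval benchmarking: per-query metrics, strategy comparison, grid search.

Four metrics summarize a retrieval result: how many returned samples are
significantly enriched for the query gene set; mean cosine similarity between
the query text and the returned studies' metadata embeddings; mean pairwise
L1 distance between the returned studies' transcriptome embeddings; and mean
pairwise cosine distance between their metadata embeddings. The interpoint
distances are not used anywhere in retrieval itself, so they serve as
independent checks. Sample-set overlap between strategies is measured with
the normalized Jaccard distance.

Strategy comparison counts, per query, whether one strategy strictly beats
another on each metric (greater is better for enrichment and query cosine,
smaller for the two interpoint distances; ties are reported separately) and
tests paired per-query metrics with a Wilcoxon signed-rank test and pooled
enriched/not-enriched counts with Fisher's exact test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist

from .corpus import Corpus, GeneSet
from .enrichment import DEFAULT_ALPHA, DEFAULT_FDR, filter_enriched
from .retrieval import (
    QueryResult,
    SearchIndex,
    StrategyId,
    run_strategy,
)
from .embed_text import embed_query

__all__ = [
    "DegenerateTestError",
    "MetricReport",
    "Query",
    "compare_strategies",
    "fisher_exact_2x2",
    "grid_search",
    "mean_interpoint_distance",
    "mean_query_cosine",
    "normalized_jaccard_distance",
    "wilcoxon_signed_rank",
]

#: metric name -> direction in which "better" points
METRIC_DIRECTIONS = {
    "n_enriched": "greater",
    "mean_query_cosine": "greater",
    "mean_l1_transcriptome": "less",
    "mean_semantic_distance": "less",
}

_PDIST_METRIC = {"l1": "cityblock", "l2": "euclidean", "cosine_dist": "cosine"}

_EXACT_WILCOXON_MAX_N = 15


class DegenerateTestError(ValueError):
    """Raised when a paired test has no non-zero differences."""


class Query(NamedTuple):
    """A benchmark item: id, free-text query, and the matching gene set."""

    query_id: str
    text: str
    gene_set: GeneSet


def mean_query_cosine(
    query_vec: np.ndarray, study_ids: Sequence[str], metadata_db
) -> float:
    """Mean cosine similarity between the query vector and given study rows."""
    if not study_ids:
        raise ValueError("empty study list")
    q = np.asarray(query_vec, dtype=np.float64)
    qnorm = np.linalg.norm(q)
    if qnorm == 0:
        raise ValueError("zero query vector")
    sims = []
    for sid in study_ids:
        v = metadata_db.vector_for(sid)
        vnorm = np.linalg.norm(v)
        sims.append(0.0 if vnorm == 0 else float(v @ q / (vnorm * qnorm)))
    return float(np.mean(sims))


def mean_interpoint_distance(vectors: np.ndarray, metric: str = "l1") -> float:
    """Mean pairwise distance over all unordered pairs of row vectors."""
    vectors = np.asarray(vectors, dtype=np.float64)
    if vectors.ndim != 2 or vectors.shape[0] < 2:
        raise ValueError("undefined interpoint distance: need >= 2 vectors")
    try:
        scipy_metric = _PDIST_METRIC[metric]
    except KeyError:
        raise ValueError(
            f"unknown metric {metric!r}; available: {sorted(_PDIST_METRIC)}"
        ) from None
    return float(pdist(vectors, metric=scipy_metric).mean())


def normalized_jaccard_distance(a: set, b: set) -> float:
    """1 - |a & b| / |a | b|; two empty sets are at distance 0."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return 1.0 - len(a & b) / len(union)


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test, two-sided.

    Zero differences are dropped. For n <= 15 remaining pairs the p-value is
    exact, from full enumeration of all 2^n sign assignments of the midranked
    |differences| (this handles ties, unlike the textbook null table); larger
    n uses the normal approximation.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise DegenerateTestError("degenerate test: all differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    if n <= _EXACT_WILCOXON_MAX_N:
        w_all = np.array(
            [sum(r for r, s in zip(ranks, signs) if s) for signs in itertools.product((False, True), repeat=n)]
        )
        total = w_all.size
        p_le = np.count_nonzero(w_all <= w_obs + 1e-12) / total
        p_ge = np.count_nonzero(w_all >= w_obs - 1e-12) / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        _, p = stats.wilcoxon(d, method="approx")
        p = float(p)
    return w_obs, p


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p for a 2x2 contingency table.

    Sums hypergeometric probabilities of tables (with the observed margins)
    no more probable than the observed one. A zero margin gives p = 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with non-negative integer entries")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


@dataclass
class MetricReport:
    """Per-query metric rows plus pairwise win/tie/loss summary with tests."""

    rows: pd.DataFrame
    summary: pd.DataFrame


def _metric_row(
    result: QueryResult,
    query: Query,
    index: SearchIndex,
    corpus: Corpus,
    alpha: float,
    n_perm: int,
    seed: int,
    fdr: float,
) -> dict:
    table, retained = filter_enriched(
        result, corpus, query.gene_set, threshold=fdr, alpha=alpha, n_perm=n_perm, seed=seed
    )
    qvec = embed_query(query.text, index.embedder)
    row = {
        "query_id": query.query_id,
        "strategy": result.strategy.value,
        "n_returned": len(result.samples),
        "n_enriched": len(retained),
        "mean_query_cosine": mean_query_cosine(qvec, result.studies, index.metadata_db)
        if result.studies
        else np.nan,
    }
    tx_rows = [index.transcriptome_rows_of(s) for s in result.studies]
    tx = np.vstack([r for r in tx_rows if r.size]) if result.studies else np.empty((0, 0))
    row["mean_l1_transcriptome"] = (
        mean_interpoint_distance(tx, "l1") if tx.shape[0] >= 2 else np.nan
    )
    meta_vecs = np.vstack([index.metadata_db.vector_for(s) for s in result.studies]) if result.studies else np.empty((0, 0))
    row["mean_semantic_distance"] = (
        mean_interpoint_distance(meta_vecs, "cosine_dist") if meta_vecs.shape[0] >= 2 else np.nan
    )
    return row


def compare_strategies(
    queries: Sequence[Query],
    strategies: Sequence[StrategyId | str],
    index: SearchIndex,
    corpus: Corpus,
    n_search: int = 10,
    n_expand: int = 10,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = 99,
    seed: int = 0,
    fdr: float = DEFAULT_FDR,
) -> MetricReport:
    """Run every strategy on every query and summarize pairwise performance.

    The first strategy in ``strategies`` is the baseline; every other
    strategy is compared against it. Per metric, the win proportion is the
    fraction of queries where the baseline is strictly better in the metric's
    direction; ties and losses are reported alongside so the three sum to 1.
    Paired per-query metrics get a Wilcoxon signed-rank p; pooled
    enriched/not-enriched sample counts get a Fisher exact p.
    """
    if not queries:
        raise ValueError("need at least one query")
    strategies = [StrategyId(s) for s in strategies]
    rows = []
    for query in queries:
        for strategy in strategies:
            try:
                result = run_strategy(
                    strategy,
                    index,
                    query_text=query.text,
                    gene_set=query.gene_set,
                    n_search=n_search,
                    n_expand=n_expand,
                )
                rows.append(
                    _metric_row(result, query, index, corpus, alpha, n_perm, seed, fdr)
                )
            except Exception as exc:
                warnings.warn(
                    f"strategy {strategy.value} failed on query {query.query_id}: {exc}",
                    stacklevel=2,
                )
                rows.append(
                    {
                        "query_id": query.query_id,
                        "strategy": strategy.value,
                        "n_returned": np.nan,
                        "n_enriched": np.nan,
                        "mean_query_cosine": np.nan,
                        "mean_l1_transcriptome": np.nan,
                        "mean_semantic_distance": np.nan,
                    }
                )
    rows_df = pd.DataFrame(rows)

    baseline = strategies[0].value
    summary_rows = []
    for other in (s.value for s in strategies[1:]):
        for metric, direction in METRIC_DIRECTIONS.items():
            a = rows_df[rows_df["strategy"] == baseline].set_index("query_id")[metric]
            b = rows_df[rows_df["strategy"] == other].set_index("query_id")[metric]
            paired = pd.concat([a, b], axis=1, keys=["a", "b"]).dropna()
            n = len(paired)
            if n == 0:
                continue
            diff = paired["a"] - paired["b"]
            if direction == "less":
                diff = -diff
            wins = int((diff > 0).sum())
            ties = int((diff == 0).sum())
            losses = n - wins - ties
            try:
                _, wilcoxon_p = wilcoxon_signed_rank(paired["a"], paired["b"])
            except DegenerateTestError:
                wilcoxon_p = np.nan
            fisher_p = np.nan
            if metric == "n_enriched":
                ra = rows_df[rows_df["strategy"] == baseline]
                rb = rows_df[rows_df["strategy"] == other]
                ea, na = ra["n_enriched"].sum(), ra["n_returned"].sum()
                eb, nb = rb["n_enriched"].sum(), rb["n_returned"].sum()
                if np.isfinite([ea, na, eb, nb]).all():
                    fisher_p = fisher_exact_2x2(
                        [[int(ea), int(na - ea)], [int(eb), int(nb - eb)]]
                    )
            summary_rows.append(
                {
                    "baseline": baseline,
                    "other": other,
                    "metric": metric,
                    "n_queries": n,
                    "win_prop": wins / n,
                    "tie_prop": ties / n,
                    "loss_prop": losses / n,
                    "wilcoxon_p": wilcoxon_p,
                    "fisher_p": fisher_p,
                }
            )
    return MetricReport(rows=rows_df, summary=pd.DataFrame(summary_rows))


def grid_search(
    n_search_values: Sequence[int],
    n_expand_values: Sequence[int],
    queries: Sequence[Query],
    index: SearchIndex,
    corpus: Corpus,
    strategy: StrategyId | str = StrategyId.S_PLUS_T,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = 99,
    seed: int = 0,
    fdr: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """Evaluate (n_search, n_expand) cells on tuning queries.

    Each cell reports mean n_returned, mean n_enriched and mean query cosine
    over the tuning queries. No argmax is taken: the grid is returned (and
    serialized by the CLI) for manual inspection. A failing cell is marked
    rather than aborting the grid.
    """
    if not n_search_values or not n_expand_values:
        raise ValueError("grid must be non-empty")
    strategy = StrategyId(strategy)
    cells = []
    for ns in n_search_values:
        for ne in n_expand_values:
            cell = {"n_search": ns, "n_expand": ne, "failed": False}
            try:
                rows = []
                for query in queries:
                    result = run_strategy(
                        strategy,
                        index,
                        query_text=query.text,
                        gene_set=query.gene_set,
                        n_search=ns,
                        n_expand=ne,
                    )
                    rows.append(
                        _metric_row(result, query, index, corpus, alpha, n_perm, seed, fdr)
                    )
                df = pd.DataFrame(rows)
                cell["n_returned"] = float(df["n_returned"].mean())
                cell["n_enriched"] = float(df["n_enriched"].mean())
                cell["mean_query_cosine"] = float(df["mean_query_cosine"].mean())
            except Exception as exc:
                warnings.warn(
                    f"grid cell (n_search={ns}, n_expand={ne}) failed: {exc}",
                    stacklevel=2,
                )
                cell.update(
                    failed=True, n_returned=np.nan, n_enriched=np.nan, mean_query_cosine=np.nan
                )
            cells.append(cell)
    return pd.DataFrame(cells)
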