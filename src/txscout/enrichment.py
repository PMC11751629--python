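"""Single-sample GSEA scoring and permutation-based relevance filtering.

The enrichment score (ES) of a gene set S in one sample ranks all n genes by
expression (descending, ties by gene id) and walks down the list accumulating

    P_in(i)  = sum_{j<=i, g_j in S} r_j^alpha / sum_{g in S} r_g^alpha
    P_out(i) = sum_{j<=i, g_j not in S} 1 / (n - |S|)

where r_j = n - j + 1 is the descending rank weight of position j. The ES is
the sum of P_in - P_out over all positions, so a set concentrated at the top
of the ranking scores positive and one at the bottom scores negative. At
alpha = 0 every member gene weighs equally and reversing the ranking negates
the score. Ranks are taken on raw counts (the score is monotone-invariant).

Significance comes from a gene-label permutation null: set membership is
reassigned to random genes (the same permutations shared across samples), and
p = (1 + #{ES_perm >= ES_obs}) / (1 + n_perm). Benjamini-Hochberg adjustment
across samples then supports the FDR < 0.05 retrieval filter.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .corpus import Corpus, GeneSet
from .retrieval import QueryResult

__all__ = [
    "DEFAULT_ALPHA",
    "EnrichmentError",
    "bh_adjust",
    "filter_enriched",
    "permutation_pvalues",
    "ssgsea_es",
    "ssgsea_matrix",
]

DEFAULT_ALPHA = 0.25
DEFAULT_N_PERM = 199
DEFAULT_FDR = 0.05


class EnrichmentError(ValueError):
    """Raised on degenerate enrichment inputs (empty overlap, full overlap...)."""


def _membership(gene_ids: Sequence[str], gene_set: GeneSet | frozenset[str]) -> np.ndarray:
    members = gene_set.genes if isinstance(gene_set, GeneSet) else gene_set
    in_set = np.fromiter((g in members for g in gene_ids), dtype=bool, count=len(gene_ids))
    n, m = in_set.size, int(in_set.sum())
    if m == 0:
        raise EnrichmentError("gene set shares no genes with the expression universe")
    if m == n:
        raise EnrichmentError("gene set covers the whole universe; ES is undefined")
    return in_set


def _order_desc(expr: np.ndarray, gene_ids: Sequence[str]) -> np.ndarray:
    """Indices sorting genes by descending expression, ties by gene id."""
    # lexsort: last key is primary.
    return np.lexsort((np.asarray(gene_ids, dtype=object), -np.asarray(expr, dtype=np.float64)))


def _es_from_ordered(in_set_ordered: np.ndarray, alpha: float) -> float:
    n = in_set_ordered.size
    m = int(in_set_ordered.sum())
    ranks = np.arange(n, 0, -1, dtype=np.float64)  # r_j = n - j + 1
    w = np.where(in_set_ordered, ranks**alpha, 0.0)
    p_in = np.cumsum(w) / w.sum()
    p_out = np.cumsum(~in_set_ordered) / (n - m)
    return float(np.sum(p_in - p_out))


def ssgsea_es(
    expr: np.ndarray,
    gene_ids: Sequence[str],
    gene_set: GeneSet | frozenset[str],
    alpha: float = DEFAULT_ALPHA,
) -> float:
    """Single-sample enrichment score of ``gene_set`` in one expression vector."""
    expr = np.asarray(expr, dtype=np.float64)
    if expr.shape[0] != len(gene_ids):
        raise ValueError(f"{expr.shape[0]} expression values for {len(gene_ids)} genes")
    if not np.all(np.isfinite(expr)):
        raise ValueError("expression vector contains non-finite values")
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    in_set = _membership(gene_ids, gene_set)
    order = _order_desc(expr, gene_ids)
    return _es_from_ordered(in_set[order], alpha)


def ssgsea_matrix(
    counts: np.ndarray,
    sample_ids: Sequence[str],
    gene_ids: Sequence[str],
    gene_set: GeneSet | frozenset[str],
    alpha: float = DEFAULT_ALPHA,
) -> pd.Series:
    """ES per sample column of a genes x samples matrix."""
    counts = np.asarray(counts, dtype=np.float64)
    if counts.shape[1] != len(sample_ids):
        raise ValueError(f"{counts.shape[1]} columns for {len(sample_ids)} sample ids")
    out = np.empty(len(sample_ids), dtype=np.float64)
    for j, sid in enumerate(sample_ids):
        try:
            out[j] = ssgsea_es(counts[:, j], gene_ids, gene_set, alpha)
        except (ValueError, EnrichmentError) as exc:
            raise type(exc)(f"sample {sid}: {exc}") from exc
    return pd.Series(out, index=list(sample_ids), name="es")


def permutation_pvalues(
    counts: np.ndarray,
    sample_ids: Sequence[str],
    gene_ids: Sequence[str],
    gene_set: GeneSet | frozenset[str],
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> tuple[pd.Series, pd.Series]:
    """Gene-label permutation p-values per sample (shared permutations).

    Returns (es, p). For each permutation, set membership moves to a random
    gene subset of the same size and the ES is recomputed for every sample;
    p = (1 + #{ES_perm >= ES_obs}) / (1 + n_perm), hence always in (0, 1].
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    counts = np.asarray(counts, dtype=np.float64)
    n_genes, n_samples = counts.shape
    if n_samples != len(sample_ids):
        raise ValueError(f"{n_samples} columns for {len(sample_ids)} sample ids")
    in_set = _membership(gene_ids, gene_set)
    m = int(in_set.sum())

    # One descending-order index per sample, reused across permutations.
    orders = np.empty((n_samples, n_genes), dtype=np.intp)
    for j in range(n_samples):
        orders[j] = _order_desc(counts[:, j], gene_ids)

    ranks = np.arange(n_genes, 0, -1, dtype=np.float64)
    rank_w = ranks**alpha

    def es_all(membership: np.ndarray) -> np.ndarray:
        mo = membership[orders]  # samples x genes, ordered per sample
        w = np.where(mo, rank_w[None, :], 0.0)
        p_in = np.cumsum(w, axis=1) / w.sum(axis=1, keepdims=True)
        p_out = np.cumsum(~mo, axis=1) / (n_genes - m)
        return (p_in - p_out).sum(axis=1)

    es_obs = es_all(in_set)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_samples, dtype=np.int64)
    for _ in range(n_perm):
        perm_membership = np.zeros(n_genes, dtype=bool)
        perm_membership[rng.choice(n_genes, size=m, replace=False)] = True
        exceed += es_all(perm_membership) >= es_obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    idx = list(sample_ids)
    return pd.Series(es_obs, index=idx, name="es"), pd.Series(pvals, index=idx, name="p")


def bh_adjust(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to input order."""
    p = np.asarray(pvals, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_enriched(
    result: QueryResult,
    corpus: Corpus,
    gene_set: GeneSet,
    threshold: float = DEFAULT_FDR,
    alpha: float = DEFAULT_ALPHA,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Keep retrieved samples significantly enriched for the query gene set.

    Returns the per-sample enrichment table (sample_id, es, p, q, enriched)
    and the list of retained sample ids (q < ``threshold``).
    """
    sample_ids = result.samples
    if not sample_ids:
        warnings.warn("query result contains no samples; nothing to filter", stacklevel=2)
        empty = pd.DataFrame(columns=["sample_id", "es", "p", "q", "enriched"])
        return empty, []
    col_index = corpus.sample_index()
    missing = [s for s in sample_ids if s not in col_index]
    if missing:
        raise ValueError(f"result samples absent from corpus: {missing[:5]}")
    cols = [col_index[s] for s in sample_ids]
    sub = np.asarray(corpus.counts, dtype=np.float64)[:, cols]
    es, p = permutation_pvalues(
        sub, sample_ids, corpus.gene_ids, gene_set, alpha=alpha, n_perm=n_perm, seed=seed
    )
    q = bh_adjust(p.to_numpy())
    # q lies in (0, 1], so threshold >= 1 means "keep everything" even for q == 1.
    enriched = np.ones_like(q, dtype=bool) if threshold >= 1.0 else q < threshold
    table = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "es": es.to_numpy(),
            "p": p.to_numpy(),
            "q": q,
            "enriched": enriched,
        }
    )
    retained = table.loc[table["enriched"], "sample_id"].tolist()
    return table, retained
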