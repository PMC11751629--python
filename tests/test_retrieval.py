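"""Cosine kNN correctness and the two-stage retrieval strategies."""

import numpy as np
import pytest

from txscout import (
    EmbeddingDB,
    GeneSet,
    HashingTextEmbedder,
    SearchIndex,
    StrategyId,
    knn_cosine,
    make_query,
    run_strategy,
    search_semantic,
    search_transcriptome,
)
from txscout.corpus import Corpus, SampleRecord, StudyRecord, assemble_study_text
from txscout.retrieval import (
    DegenerateQueryError,
    EmptyDatabaseError,
    Hit,
    StrategyQueryError,
    expand,
)


def make_db(vectors, ids=None):
    vectors = np.asarray(vectors, dtype=float)
    ids = ids or [f"id{i}" for i in range(vectors.shape[0])]
    return EmbeddingDB(ids=ids, vectors=vectors)


class TestKnnCosine:
    def test_query_equal_to_row_scores_one_first(self):
        db = make_db([[1, 2, 2], [0, 1, 0]])
        hits = knn_cosine(np.array([1.0, 2.0, 2.0]), db, 1)
        assert hits[0][0] == "id0"
        assert hits[0][1] == pytest.approx(1.0)

    def test_orthogonal_rows_score_zero(self):
        db = make_db([[1, 0], [0, 1]])
        hits = knn_cosine(np.array([1.0, 0.0]), db, 2)
        assert [h[1] for h in hits] == pytest.approx([1.0, 0.0])

    def test_hand_computed_cosine(self):
        # dot([1,2,2],[2,1,2]) = 8; norms are both 3 -> 8/9
        db = make_db([[2, 1, 2]])
        ((_, score),) = knn_cosine(np.array([1.0, 2.0, 2.0]), db, 1)
        assert score == pytest.approx(8 / 9, abs=1e-12)

    def test_ties_break_lexicographically(self):
        db = make_db([[1, 0], [2, 0], [0, 1]], ids=["b", "a", "c"])
        hits = knn_cosine(np.array([1.0, 0.0]), db, 3)
        assert [h[0] for h in hits] == ["a", "b", "c"]

    def test_n_larger_than_db_returns_all(self):
        db = make_db([[1, 0], [0, 1]])
        assert len(knn_cosine(np.array([1.0, 1.0]), db, 10)) == 2

    def test_zero_query_raises_degenerate(self):
        db = make_db([[1, 0]])
        with pytest.raises(DegenerateQueryError):
            knn_cosine(np.zeros(2), db, 1)

    def test_empty_db_raises(self):
        db = EmbeddingDB(ids=[], vectors=np.zeros((0, 2)))
        with pytest.raises(EmptyDatabaseError):
            knn_cosine(np.ones(2), db, 1)

    def test_agrees_with_exhaustive_argsort_oracle(self):
        """Exact agreement with a brute-force scan on 100 random databases."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n, d = rng.integers(2, 12), rng.integers(2, 6)
            vectors = rng.normal(size=(n, d))
            ids = [f"r{i:02d}" for i in range(n)]
            db = make_db(vectors, ids)
            q = rng.normal(size=d)
            k = int(rng.integers(1, n + 1))
            hits = knn_cosine(q, db, k)
            # oracle: full cosine scan + stable sort on (-score, id)
            sims = [
                (float(v @ q / (np.linalg.norm(v) * np.linalg.norm(q))), i)
                for i, v in zip(ids, vectors)
            ]
            expected = sorted(sims, key=lambda t: (-t[0], t[1]))[:k]
            assert [h[0] for h in hits] == [i for _, i in expected]
            np.testing.assert_allclose(
                [h[1] for h in hits], [s for s, _ in expected], atol=1e-9
            )


class TestSemanticSearch:
    def test_planted_study_text_ranks_first(self, planted, small_index):
        corpus, _, _ = planted
        query = assemble_study_text(corpus.studies[7])
        hits = search_semantic(query, small_index.metadata_db, small_index.embedder, 5)
        assert hits[0].study_id == corpus.studies[7].study_id

    def test_topic_vocabulary_query_recovers_topic(self, planted, small_index):
        corpus, truth, topics = planted
        text, _ = make_query(topics[2], seed=9)
        hits = search_semantic(text, small_index.metadata_db, small_index.embedder, 10)
        same = sum(truth[h.study_id] == "topic2" for h in hits)
        assert same >= 8

    def test_n_search_one_returns_one_hit(self, small_index):
        hits = search_semantic("anything at all", small_index.metadata_db, small_index.embedder, 1)
        assert len(hits) == 1


class TestTranscriptomeSearch:
    def test_signature_gene_set_recovers_topic(self, planted, small_index):
        corpus, truth, topics = planted
        _, gs = make_query(topics[1], seed=3)
        hits = search_transcriptome(
            gs, small_index.transcriptome_db, small_index.projector,
            small_index.gene_ids, 5,
        )
        assert truth[hits[0].study_id] == "topic1"

    def test_duplicated_conditions_collapse_to_one_study(self):
        emb = HashingTextEmbedder(dim=16)
        counts = np.array([[10, 10, 1], [1, 1, 10]])
        corpus = Corpus(
            counts=counts,
            gene_ids=["g1", "g2"],
            samples=[
                SampleRecord("S1", "ST1", "a"),
                SampleRecord("S2", "ST1", "b"),
                SampleRecord("S3", "ST2", "a"),
            ],
            studies=[StudyRecord("ST1", "t"), StudyRecord("ST2", "t")],
        )
        index = SearchIndex.build(corpus, embedder=emb, k=2, jl_seed=0)
        gs = GeneSet("q", "", frozenset({"g1"}))
        hits = search_transcriptome(
            gs, index.transcriptome_db, index.projector, index.gene_ids, 10
        )
        assert [h.study_id for h in hits].count("ST1") == 1

    def test_n_larger_than_db_returns_all_studies(self, planted, small_index):
        corpus, _, topics = planted
        _, gs = make_query(topics[0], seed=3)
        hits = search_transcriptome(
            gs, small_index.transcriptome_db, small_index.projector,
            small_index.gene_ids, 10_000,
        )
        assert len(hits) == len(corpus.studies)


class TestExpand:
    def test_transcriptome_duplicate_found_with_score_one(self):
        emb = HashingTextEmbedder(dim=16)
        counts = np.array([[5, 5, 1], [2, 2, 9]])
        corpus = Corpus(
            counts=counts,
            gene_ids=["g1", "g2"],
            samples=[
                SampleRecord("S1", "A", "c"),
                SampleRecord("S2", "B", "c"),
                SampleRecord("S3", "C", "c"),
            ],
            studies=[StudyRecord("A", "ta"), StudyRecord("B", "tb"), StudyRecord("C", "tc")],
        )
        index = SearchIndex.build(corpus, embedder=emb, k=2, jl_seed=1)
        hits = expand([Hit("A", 1.0)], "transcriptome", index, 2)
        by_id = {h.study_id: h for h in hits}
        assert by_id["B"].score == pytest.approx(1.0)  # exact duplicate column
        assert by_id["B"].seed_study == "A"

    def test_zero_expansion_is_empty(self, small_index):
        assert expand([Hit("SYN00000", 1.0)], "semantic", small_index, 0) == []

    def test_seed_excluded_from_own_expansion(self, small_index):
        hits = expand([Hit("SYN00000", 1.0)], "semantic", small_index, 10)
        assert all(h.study_id != "SYN00000" for h in hits)

    def test_disjoint_seed_neighborhoods_union_sizes_add(self):
        # two orthogonal planted blocks: seeds expand into disjoint sets
        emb = HashingTextEmbedder(dim=16)
        n = 8
        counts = np.zeros((4, n), dtype=int)
        counts[0, :2] = 100
        counts[1, 2:4] = 100
        counts[2, 4:6] = 100
        counts[3, 6:8] = 100
        studies = [StudyRecord(f"ST{i}", f"t{i}") for i in range(n)]
        samples = [SampleRecord(f"S{i}", f"ST{i}", "c") for i in range(n)]
        corpus = Corpus(counts=counts, gene_ids=list("abcd"), samples=samples, studies=studies)
        index = SearchIndex.build(corpus, embedder=emb, k=4, jl_seed=0)
        hits = expand(
            [Hit("ST0", 1.0), Hit("ST2", 1.0)], "transcriptome", index, 1
        )
        assert len(hits) == 2
        assert {h.study_id for h in hits} == {"ST1", "ST3"}

    def test_unknown_seed_skipped_with_warning(self, small_index):
        with pytest.warns(UserWarning, match="absent"):
            hits = expand([Hit("NOPE", 1.0)], "semantic", small_index, 3)
        assert hits == []


class TestRunStrategy:
    def test_s_only_equals_search_semantic(self, planted, small_index):
        _, _, topics = planted
        text, _ = make_query(topics[0], seed=4)
        result = run_strategy("s", small_index, query_text=text, n_search=5)
        direct = search_semantic(text, small_index.metadata_db, small_index.embedder, 5)
        assert result.stage1 == direct
        assert result.stage2 == []
        assert result.studies == [h.study_id for h in direct]

    def test_splus_t_recovers_topic_over_all_returned_studies(self, planted, small_index):
        corpus, truth, topics = planted
        text, gs = make_query(topics[3], seed=5)
        result = run_strategy(
            "s+t", small_index, query_text=text, gene_set=gs, n_search=10, n_expand=10
        )
        frac = np.mean([truth[s] == "topic3" for s in result.studies])
        assert frac >= 0.8

    def test_mismatched_query_type_rejected(self, planted, small_index):
        _, _, topics = planted
        _, gs = make_query(topics[0], seed=5)
        with pytest.raises(StrategyQueryError):
            run_strategy("s+t", small_index, gene_set=gs)
        with pytest.raises(StrategyQueryError):
            run_strategy("t+s", small_index, query_text="text only")

    def test_deterministic_repeat_runs(self, planted, small_index):
        _, _, topics = planted
        text, gs = make_query(topics[1], seed=6)
        a = run_strategy("s+t", small_index, query_text=text, gene_set=gs)
        b = run_strategy("s+t", small_index, query_text=text, gene_set=gs)
        assert a == b

    def test_empty_query_raises_degenerate(self, small_index):
        with pytest.raises(DegenerateQueryError):
            run_strategy("s", small_index, query_text="")

    @pytest.mark.parametrize("strategy", ["s", "s+t", "s+s"])
    def test_monotone_in_n_search(self, planted, small_index, strategy):
        """Growing n_search never drops a previously returned study."""
        _, _, topics = planted
        text, gs = make_query(topics[2], seed=7)
        small = run_strategy(
            strategy, small_index, query_text=text, gene_set=gs, n_search=3, n_expand=4
        )
        large = run_strategy(
            strategy, small_index, query_text=text, gene_set=gs, n_search=6, n_expand=4
        )
        assert set(small.studies) <= set(large.studies)

    def test_monotone_in_n_expand(self, planted, small_index):
        _, _, topics = planted
        text, gs = make_query(topics[2], seed=7)
        small = run_strategy(
            "s+t", small_index, query_text=text, gene_set=gs, n_search=5, n_expand=2
        )
        large = run_strategy(
            "s+t", small_index, query_text=text, gene_set=gs, n_search=5, n_expand=8
        )
        assert set(small.studies) <= set(large.studies)

    def test_samples_are_all_members_of_returned_studies(self, planted, small_index):
        corpus, _, topics = planted
        text, gs = make_query(topics[4], seed=8)
        result = run_strategy("s+t", small_index, query_text=text, gene_set=gs)
        membership = {s.sample_id: s.study_id for s in corpus.samples}
        assert result.samples  # non-empty
        assert {membership[s] for s in result.samples} == set(result.studies)

    def test_scores_bounded_and_sorted_within_stages(self, planted, small_index):
        _, _, topics = planted
        text, gs = make_query(topics[0], seed=9)
        result = run_strategy("t+t", small_index, gene_set=gs)
        for stage in (result.stage1, result.stage2):
            scores = [h.score for h in stage]
            assert all(-1.0 <= s <= 1.0 for s in scores)
            assert scores == sorted(scores, reverse=True)

    def test_json_round_trip(self, planted, small_index, tmp_path):
        from txscout import QueryResult

        _, _, topics = planted
        text, gs = make_query(topics[1], seed=10)
        result = run_strategy("s+t", small_index, query_text=text, gene_set=gs)
        back = QueryResult.from_json(result.to_json(tmp_path / "r.json"))
        assert back == result
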