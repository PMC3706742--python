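"""Tokenization, inverted index and BM25 ranking."""

import io
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gotextcat import bm25_score, build_index, search, tokenize
from gotextcat.porter import stem
from gotextcat.retrieval import InvertedIndex

# Input/output pairs of the published suffix-stripping algorithm, checked
# against its reference vocabulary behaviour.
PORTER_PAIRS = [
    ("caresses", "caress"), ("ponies", "poni"), ("ties", "ti"),
    ("cats", "cat"), ("feed", "feed"), ("agreed", "agre"),
    ("plastered", "plaster"), ("motoring", "motor"), ("hopping", "hop"),
    ("falling", "fall"), ("filing", "file"), ("happy", "happi"),
    ("sky", "sky"), ("relational", "relat"), ("conditional", "condit"),
    ("generalizations", "gener"), ("oscillators", "oscil"),
    ("connection", "connect"), ("regulation", "regul"),
    ("secondary", "secondari"), ("shoots", "shoot"),
    ("formation", "format"), ("controlling", "control"),
    ("adjustable", "adjust"), ("dependent", "depend"),
    ("effective", "effect"), ("triplicate", "triplic"),
]


class TestTokenize:
    @pytest.mark.parametrize("word,expected", PORTER_PAIRS)
    def test_porter_reference_pairs(self, word, expected):
        assert stem(word) == expected

    def test_stems_and_drops_stopwords(self):
        assert tokenize("Regulation of secondary shoots") == [
            "regul", "secondari", "shoot"]

    def test_empty_text(self):
        assert tokenize("") == []

    def test_all_stopwords(self):
        assert tokenize("the of and") == []

    def test_splits_on_non_alphanumeric_and_drops_short(self):
        assert tokenize("p53-mediated; a 5 x response!") == [
            "p53", "mediat", "respons"]

    def test_case_folding(self):
        assert tokenize("SHOOT Shoot shoot") == ["shoot"] * 3


class TestBuildIndex:
    def test_posting_counts(self):
        index = build_index([("d", "shoot shoot apex")])
        assert index.postings["shoot"] == [("d", 2)]
        assert index.postings["apex"] == [("d", 1)]
        assert index.doc_lengths["d"] == 3

    def test_empty_collection(self):
        index = build_index([])
        assert index.doc_count == 0
        assert index.avg_doc_length == 0.0

    def test_shared_token_has_two_postings(self):
        index = build_index([("d1", "shoot growth"), ("d2", "shoot apex")])
        assert len(index.postings["shoot"]) == 2

    def test_duplicate_doc_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_index([("d", "a b"), ("d", "c d")])

    def test_posting_frequencies_sum_to_doc_length(self, small_set):
        _onto, kb, _heldout = small_set
        index = build_index(
            (pmid, kb.documents[pmid].text) for pmid in sorted(kb.documents)
        )
        totals = {doc_id: 0 for doc_id in index.doc_lengths}
        for plist in index.postings.values():
            for doc_id, tf in plist:
                totals[doc_id] += tf
        assert totals == index.doc_lengths
        assert index.avg_doc_length == pytest.approx(
            sum(index.doc_lengths.values()) / index.doc_count)


# one token each after stemming: shoot / apex / growth
_CORPUS = [
    ("d1", "shoot shoot growth"),
    ("d2", "shoot apex"),
    ("d3", "growth apex apex"),
]


class TestBM25:
    @pytest.fixture()
    def index(self):
        return build_index(_CORPUS)

    def test_absent_token_contributes_zero(self, index):
        assert bm25_score(["apex"], "d1", index) == 0.0

    def test_unit_tf_at_average_length_equals_idf(self):
        # all documents the same length -> dl/avgdl = 1, tf = 1
        index = build_index([("d1", "shoot apex"), ("d2", "growth apex")])
        expected_idf = math.log((2 - 1 + 0.5) / (1 + 0.5) + 1)
        assert bm25_score(["shoot"], "d1", index) == pytest.approx(expected_idf)

    def test_hand_computed_three_document_fixture(self, index):
        # frozen values from direct evaluation of the scoring formula with
        # k1=1.2, b=0.75, N=3, avgdl=8/3, df(shoot)=df(apex)=2
        query = ["shoot", "apex"]
        assert bm25_score(query, "d1", index) == pytest.approx(
            0.624306707526, abs=1e-9)
        assert bm25_score(query, "d2", index) == pytest.approx(
            1.047096693003, abs=1e-9)
        assert bm25_score(query, "d3", index) == pytest.approx(
            0.624306707526, abs=1e-9)

    def test_unknown_doc_id_rejected(self, index):
        with pytest.raises(KeyError):
            bm25_score(["shoot"], "nope", index)

    def test_scores_nonnegative(self, index):
        for doc_id in index.doc_lengths:
            assert bm25_score(["shoot", "apex", "growth"], doc_id, index) >= 0


class TestSearch:
    def test_self_similarity_ranks_first(self):
        index = build_index(
            [("d1", "kinase phosphorylation cascade"), ("d2", "membrane lipid")])
        ranked = search("kinase phosphorylation cascade", index, top_n=5)
        assert ranked[0][0] == "d1"

    def test_disjoint_query_gives_empty_result(self):
        index = build_index(_CORPUS)
        assert search("ribosome translation", index, top_n=5) == []

    def test_tie_break_by_ascending_doc_id(self):
        index = build_index(_CORPUS)
        ranked = search("shoot apex", index, top_n=3)
        assert [doc_id for doc_id, _ in ranked] == ["d2", "d1", "d3"]

    def test_exclude_bars_documents(self):
        index = build_index(_CORPUS)
        ranked = search("shoot apex", index, top_n=3, exclude={"d2"})
        assert "d2" not in {doc_id for doc_id, _ in ranked}

    def test_top_n_must_be_positive(self):
        with pytest.raises(ValueError):
            search("shoot", build_index(_CORPUS), top_n=0)

    def test_ranking_invariant_under_insertion_order(self):
        forward = build_index(_CORPUS)
        backward = build_index(list(reversed(_CORPUS)))
        assert search("shoot apex growth", forward, 10) == search(
            "shoot apex growth", backward, 10)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.data())
    def test_matches_brute_force_oracle(self, data):
        vocab = ["alpha", "beta", "gamma", "delta", "epsilon", "zeta"]
        n_docs = data.draw(st.integers(1, 20))
        docs = []
        for i in range(n_docs):
            words = data.draw(st.lists(st.sampled_from(vocab), max_size=12))
            docs.append((f"d{i:03d}", " ".join(words)))
        query_words = data.draw(
            st.lists(st.sampled_from(vocab), min_size=1, max_size=6))
        query = " ".join(query_words)
        index = build_index(docs)
        ranked = search(query, index, top_n=n_docs)
        tokens = tokenize(query)
        brute = sorted(
            (
                (doc_id, bm25_score(tokens, doc_id, index))
                for doc_id, _ in docs
            ),
            key=lambda item: (-item[1], item[0]),
        )
        brute = [(d, s) for d, s in brute if s > 0]
        assert [d for d, _ in ranked] == [d for d, _ in brute]
        for (_, got), (_, want) in zip(ranked, brute):
            assert got == pytest.approx(want, abs=1e-9)


class TestPersistence:
    def test_save_load_roundtrip(self, small_set):
        _onto, kb, _heldout = small_set
        index = build_index(
            (pmid, kb.documents[pmid].text) for pmid in sorted(kb.documents))
        buffer = io.StringIO()
        index.save(buffer)
        buffer.seek(0)
        loaded = InvertedIndex.load(buffer)
        assert loaded.doc_lengths == index.doc_lengths
        assert loaded.postings == index.postings
        assert (loaded.k1, loaded.b) == (index.k1, index.b)

    def test_versioned_header_checked(self):
        with pytest.raises(ValueError, match="not a gotextcat index"):
            InvertedIndex.load(io.StringIO('{"format": "something-else"}\n'))
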