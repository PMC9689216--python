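"""Corpus preparation: term counting, TF-IDF ranking, synonym merging and
panel assembly."""

import json
import math

import numpy as np
import pandas as pd
import pytest

from tgnet.corpus import (
    Document,
    KeywordSet,
    PanelData,
    build_panel,
    count_terms,
    merge_synonyms,
    quarter_of,
    read_jsonl_corpus,
    tfidf_rank,
)


def _doc(i, date, tokens):
    return Document(str(i), date, tokens)


@pytest.fixture()
def fixture_corpus():
    return [
        _doc(1, "2015-01-10", ["apple", "banana", "apple", "date"]),
        _doc(2, "2015-02-15", ["banana", "cherry", "cherry", "cherry"]),
        _doc(3, "2015-03-20", ["apple", "date", "date"]),
    ]


class TestCountTerms:
    def test_direct_count(self):
        table = count_terms([_doc(1, "2020-01-01", ["a", "b", "a"])])
        assert table.loc["1", "a"] == 2 and table.loc["1", "b"] == 1

    def test_stopword_filter(self):
        table = count_terms([_doc(1, "2020-01-01", ["a", "b", "a"])], {"a"})
        assert list(table.columns) == ["b"]

    def test_fixture_hand_count(self, fixture_corpus):
        table = count_terms(fixture_corpus)
        # hand enumeration of the 3-document fixture
        expected = pd.DataFrame(
            {
                "apple": [2.0, 0.0, 1.0],
                "banana": [1.0, 1.0, 0.0],
                "cherry": [0.0, 3.0, 0.0],
                "date": [1.0, 0.0, 2.0],
            },
            index=["1", "2", "3"],
        )
        pd.testing.assert_frame_equal(table, expected)

    def test_punctuation_only_tokens_dropped(self):
        table = count_terms([_doc(1, "2020-01-01", ["a", "!!", "--", "b"])])
        assert set(table.columns) == {"a", "b"}

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            count_terms([])


class TestTfidfRank:
    def test_ubiquitous_term_scores_zero(self, fixture_corpus):
        ranked = tfidf_rank(count_terms(fixture_corpus), K=4)
        # banana appears in 2 of 3 docs, apple in 2, cherry in 1, date in 2
        assert ranked["cherry"] == pytest.approx(3 * math.log(3))

    def test_formula_evaluation(self):
        docs = [_doc(1, "2020-01-01", ["x"] * 3), _doc(2, "2020-01-02", ["y"])]
        ranked = tfidf_rank(count_terms(docs), K=2)
        assert ranked["x"] == pytest.approx(3 * math.log(2))

    def test_term_in_every_document_ranked_last(self):
        docs = [
            _doc(1, "2020-01-01", ["common", "rare1"]),
            _doc(2, "2020-01-02", ["common", "rare2"]),
        ]
        ranked = tfidf_rank(count_terms(docs), K=3)
        assert ranked.index[-1] == "common"
        assert ranked["common"] == 0.0

    def test_top3_matches_brute_force(self, rng):
        vocab = [f"t{i}" for i in range(12)]
        docs = [
            _doc(i, "2020-01-01", list(rng.choice(vocab, size=rng.integers(3, 15))))
            for i in range(5)
        ]
        table = count_terms(docs)
        ranked = tfidf_rank(table, K=3)
        # exhaustive oracle: per-document f * ln(N/df), corpus score = max
        N = len(docs)
        df = (table > 0).sum(axis=0)
        scores = (table * np.log(N / df)).max(axis=0)
        oracle = scores.sort_index().sort_values(ascending=False, kind="stable").iloc[:3]
        assert list(ranked.index) == list(oracle.index)

    def test_duplicating_corpus_leaves_ranking_invariant(self, fixture_corpus):
        base = tfidf_rank(count_terms(fixture_corpus), K=4)
        doubled_docs = fixture_corpus + [
            _doc(f"{d.id}-copy", d.date, list(d.tokens)) for d in fixture_corpus
        ]
        doubled = tfidf_rank(count_terms(doubled_docs), K=4)
        assert list(base.index) == list(doubled.index)
        np.testing.assert_allclose(base.values, doubled.values)

    def test_k_above_vocabulary_returns_all(self, fixture_corpus):
        ranked = tfidf_rank(count_terms(fixture_corpus), K=100)
        assert len(ranked) == 4


class TestMergeSynonyms:
    def test_additive_merge(self):
        table = pd.DataFrame({"doctor": [2.0], "physician": [1.0]}, index=["1"])
        merged = merge_synonyms(table, {"physician": "doctor"})
        assert merged.loc["1", "doctor"] == 3.0

    def test_empty_map_is_identity(self):
        table = pd.DataFrame({"a": [1.0], "b": [2.0]}, index=["1"])
        pd.testing.assert_frame_equal(merge_synonyms(table, {}), table)

    def test_three_way_merge(self):
        table = pd.DataFrame({"md": [1.0], "doc": [2.0], "doctor": [4.0]}, index=["1"])
        merged = merge_synonyms(table, {"md": "doctor", "doc": "doctor"})
        assert merged.loc["1", "doctor"] == 7.0
        assert list(merged.columns) == ["doctor"]

    def test_chained_map_rejected(self):
        table = pd.DataFrame({"a": [1.0]}, index=["1"])
        with pytest.raises(ValueError, match="chained"):
            merge_synonyms(table, {"a": "b", "b": "c"})


class TestBuildPanel:
    def test_adjusted_frequency_formula(self):
        doc = _doc(1, "2019-05-01", ["kw"] * 2 + ["x"] * 8)
        kws = KeywordSet(["kw"])
        panel = build_panel([doc], kws, scale=1000.0)
        assert panel.matrices[0][0, 0] == pytest.approx(200.0)

    def test_absent_keyword_zero(self):
        doc = _doc(1, "2019-05-01", ["x", "y"])
        panel = build_panel([doc], KeywordSet(["kw"]))
        assert panel.matrices[0][0, 0] == 0.0

    def test_doubling_counts_leaves_row_unchanged(self):
        tokens = ["kw", "x", "x", "y"]
        p1 = build_panel([_doc(1, "2019-05-01", tokens)], KeywordSet(["kw"]))
        p2 = build_panel([_doc(1, "2019-05-01", tokens * 2)], KeywordSet(["kw"]))
        np.testing.assert_allclose(p1.matrices[0], p2.matrices[0])

    def test_rows_grouped_by_quarter_in_order(self):
        docs = [
            _doc(1, "2019-05-01", ["kw"]),
            _doc(2, "2019-01-01", ["kw", "kw"]),
            _doc(3, "2019-02-01", ["x"]),
        ]
        panel = build_panel(docs, KeywordSet(["kw"]))
        assert panel.periods == ["2019Q1", "2019Q2"]
        assert panel.matrices[0].shape[0] == 2

    def test_entries_invariant_to_document_order(self):
        docs = [
            _doc(1, "2019-01-01", ["kw", "x"]),
            _doc(2, "2019-02-01", ["kw", "kw"]),
        ]
        p1 = build_panel(docs, KeywordSet(["kw"]))
        p2 = build_panel(docs[::-1], KeywordSet(["kw"]))
        np.testing.assert_allclose(np.sort(p1.matrices[0], axis=0), np.sort(p2.matrices[0], axis=0))

    def test_merge_map_routes_raw_terms(self):
        doc = _doc(1, "2019-05-01", ["physician", "doctor"])
        kws = KeywordSet(["doctor"], {"physician": "doctor"})
        panel = build_panel([doc], kws, scale=1.0)
        assert panel.matrices[0][0, 0] == pytest.approx(1.0)


class TestPanelIO:
    def test_save_load_round_trip(self, tmp_path):
        kws = KeywordSet(["a", "b"])
        mats = [np.array([[1.0, 0.0], [0.5, 2.0]]), np.array([[0.0, 3.0]])]
        panel = PanelData(["2019Q1", "2019Q2"], mats, kws, scale=500.0)
        panel.save(tmp_path)
        loaded = PanelData.load(tmp_path)
        assert loaded.periods == panel.periods
        assert loaded.scale == 500.0
        for a, b in zip(loaded.matrices, panel.matrices):
            np.testing.assert_allclose(a, b)

    def test_jsonl_reader(self, tmp_path):
        path = tmp_path / "corpus.jsonl"
        rows = [
            {"id": "r1", "date": "2019-01-05", "text": "Hello World hello"},
            {"id": "r2", "date": "2019-04-05", "text": "foo bar"},
        ]
        path.write_text("\n".join(json.dumps(r) for r in rows) + "\n")
        docs = read_jsonl_corpus(path)
        assert docs[0].tokens == ["hello", "world", "hello"]
        assert quarter_of(docs[1].date) == "2019Q2"

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            PanelData(["q1"], [np.array([[-1.0]])], KeywordSet(["a"]))
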