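"""Tokenizer, inverted index bookkeeping and the TF-IDF baseline,
checked against brute-force oracles on small corpora."""

import math

import numpy as np
import pytest

from traitrank.index import (
    InvertedIndex,
    build_index,
    estimate_hits,
    tfidf_rank,
    tokenize,
)
from traitrank.query import TermVariant, expand_synonyms
from traitrank.records import Record


# -- brute-force oracles ----------------------------------------------

def record_tokens(record):
    out = []
    for text in record.attributes.values():
        out.extend(tokenize(text))
    return out


def brute_force_df(records):
    df = {}
    for rec in records:
        for term in set(record_tokens(rec)):
            df[term] = df.get(term, 0) + 1
    return df


def brute_force_cosine(query_terms, records):
    """Independent cosine VSM with weights tf * (1 + ln(N/df))."""
    n = len(records)
    df = brute_force_df(records)
    distinct = sorted(set(query_terms))
    q_norm = math.sqrt(len(distinct))
    scores = {}
    for rec in records:
        tokens = record_tokens(rec)
        tf = {}
        for t in tokens:
            tf[t] = tf.get(t, 0) + 1
        weights = {t: c * (1 + math.log(n / df[t])) for t, c in tf.items()}
        norm = math.sqrt(sum(w * w for w in weights.values()))
        dot = sum(weights.get(t, 0.0) for t in distinct)
        if dot > 0 and norm > 0:
            scores[rec.record_id] = dot / (q_norm * norm)
    return scores


def random_corpus(rng, n_records, vocab=("aa", "bb", "cc", "dd", "ee", "ff")):
    records = []
    for i in range(n_records):
        n_attr = int(rng.integers(1, 3))
        attrs = {}
        for a in range(n_attr):
            length = int(rng.integers(1, 12))
            attrs[f"attr{a}"] = " ".join(
                vocab[j] for j in rng.integers(0, len(vocab), length)
            )
        records.append(Record(f"r{i:03d}", "db", attrs))
    return records


# -- tokenize ---------------------------------------------------------

@pytest.mark.parametrize(
    "text,expected",
    [
        ("", []),
        ("WUS", ["wus"]),
        ("Sucrose synthase (EC 2.4.1.13)", ["sucrose", "synthase", "ec", "13"]),
        ("heat-shock  protein 70", ["heat", "shock", "protein", "70"]),
        ("a b c", []),  # single characters are dropped
    ],
)
def test_tokenize(text, expected):
    assert tokenize(text) == expected


def test_tokenize_idempotent_on_clean_tokens():
    tokens = tokenize("Barley Morex drought TOLERANCE 2b")
    assert tokenize(" ".join(tokens)) == tokens


# -- index construction -----------------------------------------------

def test_empty_corpus():
    index = build_index([])
    assert index.n_records == 0
    assert index.vocabulary == set()


def test_df_counts_documents_not_occurrences():
    index = build_index([Record("r1", "db", {"a": "barley barley"})])
    assert index.df["barley"] == 1
    assert index.cf["barley"] == 2
    (posting,) = index.postings("barley")
    assert posting.positions == (0, 1)


def test_duplicate_record_id_rejected():
    rec = Record("r1", "db", {"a": "barley"})
    with pytest.raises(ValueError, match="r1"):
        build_index([rec, rec])


def test_index_statistics_match_brute_force():
    rng = np.random.default_rng(7)
    for _ in range(5):
        records = random_corpus(rng, int(rng.integers(3, 30)))
        index = build_index(records)
        assert index.df == brute_force_df(records)
        for rec in records:
            assert index.record_token_counts[rec.record_id] == len(record_tokens(rec))
            for attr, text in rec.attributes.items():
                assert index.attribute_token_counts[(rec.record_id, attr)] == len(
                    tokenize(text)
                )
        assert all(df <= index.n_records for df in index.df.values())


def test_positional_postings_reach_per_attribute_positions(toy_index):
    positions = toy_index.term_positions("sucrose", "rec1")
    assert positions == {"description": (0,), "function": (1,)}


# -- TF-IDF ranking ---------------------------------------------------

def test_unknown_query_term_yields_empty_ranking(toy_index):
    assert tfidf_rank(["nonexistentterm"], toy_index) == []


def test_identical_single_term_document_scores_one():
    index = build_index([Record("r1", "db", {"a": "barley"})])
    ((rec, score),) = tfidf_rank(["barley"], index)
    assert rec == "r1"
    assert score == pytest.approx(1.0, abs=1e-12)


def test_tfidf_matches_brute_force_oracle():
    rng = np.random.default_rng(11)
    for _ in range(10):
        records = random_corpus(rng, int(rng.integers(3, 40)))
        index = build_index(records)
        query = ["aa", "cc"]
        expected = brute_force_cosine(query, records)
        got = dict(tfidf_rank(query, index))
        assert set(got) == set(expected)
        for rec_id, score in got.items():
            assert score == pytest.approx(expected[rec_id], abs=1e-9)
            assert 0.0 <= score <= 1.0


def test_tfidf_tie_break_is_record_id_ascending():
    records = [
        Record("r2", "db", {"a": "barley yield"}),
        Record("r1", "db", {"a": "barley yield"}),
    ]
    ranked = tfidf_rank(["barley"], build_index(records))
    assert [r for r, _ in ranked] == ["r1", "r2"]


def test_corpus_doubling_preserves_scores():
    """Duplicating the whole corpus keeps N/df, hence every score."""
    rng = np.random.default_rng(3)
    records = random_corpus(rng, 12)
    copies = [
        Record("x" + r.record_id, r.source_db, r.attributes) for r in records
    ]
    base = dict(tfidf_rank(["aa", "bb"], build_index(records)))
    doubled = dict(tfidf_rank(["aa", "bb"], build_index(records + copies)))
    for rec_id, score in base.items():
        assert doubled[rec_id] == pytest.approx(score, abs=1e-12)


def test_ranking_is_deterministic():
    rng = np.random.default_rng(5)
    records = random_corpus(rng, 25)
    r1 = tfidf_rank(["aa", "bb"], build_index(records))
    r2 = tfidf_rank(["aa", "bb"], build_index(records))
    assert r1 == r2


# -- hit estimation ---------------------------------------------------

def brute_force_hits(groups, records):
    count = 0
    for rec in records:
        tokens_by_attr = {a: tokenize(t) for a, t in rec.attributes.items()}

        def has_phrase(phrase):
            k = len(phrase)
            return any(
                list(toks[i : i + k]) == list(phrase)
                for toks in tokens_by_attr.values()
                for i in range(len(toks) - k + 1)
            )

        if all(any(has_phrase(v.tokens) for v in group) for group in groups):
            count += 1
    return count


def test_estimate_hits_empty_query(toy_index):
    assert estimate_hits(expand_synonyms([], None), toy_index) == 0


def test_estimate_hits_single_term_equals_df(toy_index):
    spec = expand_synonyms(["synthase"], None)
    assert estimate_hits(spec, toy_index) == toy_index.df["synthase"]


def test_estimate_hits_matches_brute_force_intersection():
    rng = np.random.default_rng(13)
    records = random_corpus(rng, 60)
    index = build_index(records)
    for query in (["aa"], ["aa", "bb"], ["aa", "bb", "cc"]):
        spec = expand_synonyms(query, None)
        assert estimate_hits(spec, index) == brute_force_hits(spec.groups, records)
        assert estimate_hits(spec, index) <= index.n_records


def test_estimate_hits_with_synonym_group_uses_or_semantics():
    records = [
        Record("r1", "db", {"a": "heat tolerance in maize"}),
        Record("r2", "db", {"a": "thermotolerance in maize"}),
        Record("r3", "db", {"a": "drought response"}),
    ]
    index = build_index(records)
    group = (
        TermVariant(("thermotolerance",), "exact"),
        TermVariant(("heat", "tolerance"), "synonym"),
    )
    assert estimate_hits([group], index) == 2


# -- persistence ------------------------------------------------------

def test_save_load_round_trip(tmp_path, toy_records, toy_index):
    toy_index.save(tmp_path / "idx")
    loaded = InvertedIndex.load(tmp_path / "idx")
    assert loaded.df == toy_index.df
    assert loaded.record_token_counts == toy_index.record_token_counts
    assert tfidf_rank(["barley"], loaded) == tfidf_rank(["barley"], toy_index)


def test_save_is_byte_deterministic(tmp_path, toy_records):
    build_index(toy_records).save(tmp_path / "a")
    build_index(list(reversed(toy_records))).save(tmp_path / "b")
    assert (tmp_path / "a" / "records.jsonl").read_bytes() == (
        tmp_path / "b" / "records.jsonl"
    ).read_bytes()


def test_load_rejects_non_index_directory(tmp_path):
    with pytest.raises(FileNotFoundError):
        InvertedIndex.load(tmp_path)
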