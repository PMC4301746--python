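"""The 11-dimensional relevance feature extractor."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from traitrank.features import (
    FEATURE_NAMES,
    FeatureConfig,
    build_hit_context,
    extract_features,
    keyword_context_score,
    proximity_score,
)
from traitrank.index import build_index
from traitrank.query import expand_query
from traitrank.records import Record

IDX = {name: i for i, name in enumerate(FEATURE_NAMES)}


def features_for(query, record, config=None, extra_records=()):
    index = build_index([record, *extra_records])
    spec = expand_query(query)
    ctx = build_hit_context(spec, record, index)
    return extract_features(spec, record, ctx, index, config or FeatureConfig())


# -- proximity --------------------------------------------------------

def test_single_matched_term_scores_one():
    assert proximity_score([[17]]) == 1.0


def test_adjacent_in_order_terms_score_one():
    # attribute [sucrose, synthase, activity], query "sucrose synthase"
    assert proximity_score([[0], [1]]) == pytest.approx(1.0)


def test_out_of_order_window_penalized():
    # attribute [synthase, x, sucrose]: span 3, out of query order
    assert proximity_score([[2], [0]]) == pytest.approx((2 / 3) * 0.8)


def test_reversing_two_term_window_multiplies_by_0_8():
    in_order = proximity_score([[4], [6]])
    reversed_ = proximity_score([[6], [4]])
    assert reversed_ == pytest.approx(in_order * 0.8)


def test_minimal_window_found_among_repeats():
    # term A at 0 and 10, term B at 12: best window is [10, 12]
    assert proximity_score([[0, 10], [12]]) == pytest.approx(2 / 3)


def test_three_term_window():
    assert proximity_score([[0], [2], [4]]) == pytest.approx(3 / 5)


def test_no_matched_terms_is_an_error():
    with pytest.raises(ValueError):
        proximity_score([])


# -- keyword context --------------------------------------------------

def test_empty_keyword_lists_are_neutral():
    assert keyword_context_score([2], ["a1"] * 5, FeatureConfig()) == 0.5


def test_good_keyword_near_match_scores_one():
    config = FeatureConfig(good_keywords=("characterized",))
    tokens = ["sucrose", "characterized", "pathway"]
    assert keyword_context_score([0], tokens, config) == 1.0


def test_bad_keyword_near_match_scores_zero():
    config = FeatureConfig(bad_keywords=("fragment",))
    tokens = ["sucrose", "fragment", "pathway"]
    assert keyword_context_score([0], tokens, config) == 0.0


def test_good_and_bad_cancel_to_neutral():
    config = FeatureConfig(
        good_keywords=("characterized",), bad_keywords=("fragment",)
    )
    tokens = ["characterized", "sucrose", "fragment"]
    assert keyword_context_score([1], tokens, config) == 0.5


def test_keyword_outside_window_ignored():
    config = FeatureConfig(good_keywords=("characterized",), keyword_window=2)
    tokens = ["sucrose"] + ["x1"] * 5 + ["characterized"]
    assert keyword_context_score([0], tokens, config) == 0.5


# -- full vector ------------------------------------------------------

def test_worked_example_two_term_query():
    record = Record(
        "r1", "db", {"description": "sucrose synthase activity in barley"}
    )
    f = features_for("sucrose synthase", record)
    assert len(f) == 11
    assert f[IDX["text_position_coverage"]] == pytest.approx(2 / 5)
    assert f[IDX["cooccurrence"]] == pytest.approx(1.0)
    assert f[IDX["synonym_origin"]] == 1.0
    assert f[IDX["organism_match"]] == 0.5
    assert f[IDX["sequence_length_norm"]] == 0.0
    assert f[IDX["query_coverage"]] == 1.0
    assert f[IDX["term_frequency"]] == pytest.approx(2 / 5)
    assert f[IDX["attribute_weight"]] == 0.5  # unmapped attribute
    assert f[IDX["database_weight"]] == 0.5


def test_no_match_gives_zeroes_and_neutral_categoricals():
    record = Record("r1", "db", {"description": "unrelated text entirely"})
    f = features_for("sucrose synthase", record)
    assert f[IDX["term_frequency"]] == 0.0
    assert f[IDX["cooccurrence"]] == 0.0
    assert f[IDX["text_position_coverage"]] == 0.0
    assert f[IDX["query_coverage"]] == 0.0
    assert f[IDX["synonym_origin"]] == 0.0
    assert f[IDX["keyword_context"]] == 0.5
    assert f[IDX["attribute_weight"]] == 0.5


def test_sequence_length_log_normalization():
    config = FeatureConfig(length_cap=100_000)
    record = Record(
        "r1", "db", {"description": "sucrose synthase"}, sequence_length=999
    )
    f = features_for("sucrose", record, config)
    expected = math.log10(1000) / math.log10(100_001)
    assert f[IDX["sequence_length_norm"]] == pytest.approx(expected, abs=1e-9)
    assert expected == pytest.approx(0.600, abs=0.001)


def test_length_cap_clamps_to_one():
    config = FeatureConfig(length_cap=100)
    record = Record(
        "r1", "db", {"description": "sucrose"}, sequence_length=10_000
    )
    f = features_for("sucrose", record, config)
    assert f[IDX["sequence_length_norm"]] == 1.0


def test_organism_match_through_taxonomy_aliases():
    config = FeatureConfig(taxonomy=(("barley", "hordeum vulgare"),))
    record = Record(
        "r1", "db", {"description": "salt stress"}, organism="Hordeum vulgare"
    )
    assert features_for("barley salt stress", record, config)[
        IDX["organism_match"]
    ] == 1.0
    other = Record(
        "r2", "db", {"description": "salt stress"}, organism="Zea mays"
    )
    assert features_for("barley salt stress", other, config)[
        IDX["organism_match"]
    ] == 0.0
    # query silent about organism -> neutral
    assert features_for("salt stress", record, config)[IDX["organism_match"]] == 0.5


def test_attribute_and_database_weights_come_from_config():
    config = FeatureConfig(
        attribute_weights={"description": 0.9},
        database_weights={"curated": 0.8},
    )
    record = Record("r1", "curated", {"description": "sucrose synthase"})
    f = features_for("sucrose", record, config)
    assert f[IDX["attribute_weight"]] == 0.9
    assert f[IDX["database_weight"]] == 0.8


def test_synonym_only_hit_flagged():
    from traitrank.query import SynonymTable, expand_query

    table = SynonymTable({"thermotolerance": {"bukofa"}})
    record = Record("r1", "db", {"description": "bukofa related stress"})
    index = build_index([record])
    spec = expand_query("thermotolerance", table)
    ctx = build_hit_context(spec, record, index)
    f = extract_features(spec, record, ctx, index, FeatureConfig())
    assert f[IDX["synonym_origin"]] == 0.0
    assert f[IDX["query_coverage"]] == 1.0


def test_idf_weight_favors_rare_terms():
    common = [
        Record(f"c{i}", "db", {"a": "pervasive token"}) for i in range(9)
    ]
    record = Record("r1", "db", {"a": "pervasive rareword"})
    f_rare = features_for("rareword", record, extra_records=common)
    f_common = features_for("pervasive", record, extra_records=common)
    assert f_rare[IDX["idf_weight"]] > f_common[IDX["idf_weight"]]
    assert f_rare[IDX["idf_weight"]] <= 1.0


def test_text_doubling_leaves_ratio_features_unchanged():
    base = Record("r1", "db", {"description": "sucrose synthase in barley leaf"})
    text = base.attributes["description"]
    doubled = Record("r1", "db", {"description": text + " " + text})
    f1 = features_for("sucrose synthase", base)
    f2 = features_for("sucrose synthase", doubled)
    for name in ("term_frequency", "text_position_coverage"):
        assert f1[IDX[name]] == pytest.approx(f2[IDX[name]])


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_random_corpora_yield_bounded_vectors(seed):
    rng = np.random.default_rng(seed)
    vocab = ["salt", "stress", "yield", "gene", "xx", "yy", "zz", "ww"]
    records = []
    for i in range(int(rng.integers(1, 6))):
        attrs = {
            f"a{j}": " ".join(
                vocab[k] for k in rng.integers(0, len(vocab), rng.integers(1, 15))
            )
            for j in range(int(rng.integers(1, 3)))
        }
        records.append(
            Record(
                f"r{i}",
                "db",
                attrs,
                organism="Hordeum vulgare" if rng.random() < 0.5 else None,
                sequence_length=int(rng.integers(0, 5000))
                if rng.random() < 0.5
                else None,
            )
        )
    index = build_index(records)
    config = FeatureConfig(
        good_keywords=("yield",),
        bad_keywords=("xx",),
        taxonomy=(("barley", "hordeum vulgare"),),
    )
    spec = expand_query("salt stress barley")
    for rec in records:
        ctx = build_hit_context(spec, rec, index)
        f = extract_features(spec, rec, ctx, index, config)
        assert len(f) == 11
        assert all(0.0 <= v <= 1.0 for v in f)
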