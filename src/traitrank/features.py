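"""The 11-dimensional relevance feature vector of a (query, record) hit.

Each hit is described by eleven properties, every one normalized to
[0, 1], in this fixed order:

1.  ``attribute_weight``      - configured weight of the matched attribute
2.  ``database_weight``       - configured weight of the source database
3.  ``term_frequency``        - query-term occurrences / record length
4.  ``cooccurrence``          - closeness and order of the matched terms
5.  ``keyword_context``       - good/bad keywords near the matches
6.  ``organism_match``        - query organism vs. record organism
7.  ``sequence_length_norm``  - log-scaled sequence length
8.  ``text_position_coverage``- fraction of the attribute covered by matches
9.  ``synonym_origin``        - 0 iff the hit exists only via synonym expansion
10. ``query_coverage``        - fraction of query term groups matched
11. ``idf_weight``            - mean normalized rarity of the matched terms

Components 1-9 correspond to the named ranking properties of the
underlying feature model (attribute, database, frequency, co-occurrence,
keyword, organism, sequence length, text position, synonym); the last
two are standard IR signals added to complete the stated 11-dimensional
input of the neural ranker, and are documented as extensions.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

from .index import InvertedIndex, tokenize
from .query import EXACT, CORRECTED, SYNONYM, QuerySpec
from .records import Record

FEATURE_NAMES: tuple[str, ...] = (
    "attribute_weight",
    "database_weight",
    "term_frequency",
    "cooccurrence",
    "keyword_context",
    "organism_match",
    "sequence_length_norm",
    "text_position_coverage",
    "synonym_origin",
    "query_coverage",
    "idf_weight",
)

N_FEATURES = len(FEATURE_NAMES)

DEFAULT_WEIGHT = 0.5


@dataclass
class FeatureConfig:
    """Tunable knobs of the feature extractor.

    ``taxonomy`` is a list of alias groups; each group lists spellings of
    the same taxon (e.g. ``["barley", "hordeum vulgare"]``) so that a
    common name in the query can match a Latin organism label on the
    record.  A bare string entry forms a singleton group.
    """

    attribute_weights: dict[str, float] = field(default_factory=dict)
    database_weights: dict[str, float] = field(default_factory=dict)
    good_keywords: tuple[str, ...] = ()
    bad_keywords: tuple[str, ...] = ()
    keyword_window: int = 5
    length_cap: int = 100_000
    taxonomy: tuple[tuple[str, ...], ...] = ()

    def __post_init__(self) -> None:
        for name, w in {**self.attribute_weights, **self.database_weights}.items():
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"weight for {name!r} outside [0,1]: {w}")
        if self.keyword_window < 1:
            raise ValueError("keyword_window must be >= 1")
        if self.length_cap < 1:
            raise ValueError("length_cap must be >= 1")
        self.good_keywords = tuple(k.lower() for k in self.good_keywords)
        self.bad_keywords = tuple(k.lower() for k in self.bad_keywords)
        self.taxonomy = tuple(
            (g.lower(),) if isinstance(g, str) else tuple(a.lower() for a in g)
            for g in self.taxonomy
        )

    # -- serialization (shared with the CLI config file) ---------------

    def to_dict(self) -> dict:
        return {
            "attribute_weights": dict(self.attribute_weights),
            "database_weights": dict(self.database_weights),
            "good_keywords": list(self.good_keywords),
            "bad_keywords": list(self.bad_keywords),
            "keyword_window": self.keyword_window,
            "length_cap": self.length_cap,
            "taxonomy": [list(g) for g in self.taxonomy],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FeatureConfig":
        return cls(
            attribute_weights=dict(d.get("attribute_weights", {})),
            database_weights=dict(d.get("database_weights", {})),
            good_keywords=tuple(d.get("good_keywords", ())),
            bad_keywords=tuple(d.get("bad_keywords", ())),
            keyword_window=int(d.get("keyword_window", 5)),
            length_cap=int(d.get("length_cap", 100_000)),
            taxonomy=tuple(tuple(g) for g in d.get("taxonomy", ())),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "FeatureConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class HitContext:
    """Where and how a query matched one record.

    ``attribute`` is the best-matching attribute (most distinct groups
    matched, then most matched positions, then attribute order), or
    ``None`` when nothing matched.  ``group_positions`` maps the index
    of each query term group to the sorted token positions its variants
    cover inside that attribute.
    """

    attribute: str | None
    group_positions: dict[int, tuple[int, ...]]
    matched_origins: frozenset[str]
    groups_matched_anywhere: frozenset[int]
    matched_terms: frozenset[str]
    total_term_occurrences: int

    def matched_positions(self) -> list[int]:
        out: set[int] = set()
        for positions in self.group_positions.values():
            out.update(positions)
        return sorted(out)


def build_hit_context(
    query_spec: QuerySpec, record: Record, index: InvertedIndex
) -> HitContext:
    """Locate every query variant in a record and pick the best attribute."""
    rid = record.record_id
    if rid not in index.records:
        raise KeyError(f"record {rid!r} not in index")
    # per attribute: group index -> set of covered positions
    per_attr: dict[str, dict[int, set[int]]] = {}
    matched_origins: set[str] = set()
    groups_anywhere: set[int] = set()
    matched_terms: set[str] = set()
    for gi, group in enumerate(query_spec.groups):
        for variant in group:
            hits = index.phrase_positions(variant.tokens, rid)
            if not hits:
                continue
            groups_anywhere.add(gi)
            matched_origins.add(variant.origin)
            matched_terms.update(variant.tokens)
            width = len(variant.tokens)
            for attr, starts in hits.items():
                slot = per_attr.setdefault(attr, {}).setdefault(gi, set())
                for s in starts:
                    slot.update(range(s, s + width))
    if not per_attr:
        return HitContext(None, {}, frozenset(), frozenset(), frozenset(), 0)
    attr_order = {a: i for i, a in enumerate(index.records[rid].attributes)}
    best = min(
        per_attr,
        key=lambda a: (
            -len(per_attr[a]),
            -sum(len(p) for p in per_attr[a].values()),
            attr_order.get(a, len(attr_order)),
        ),
    )
    group_positions = {
        gi: tuple(sorted(pos)) for gi, pos in per_attr[best].items()
    }
    total = sum(index.term_count(t, rid) for t in matched_terms)
    return HitContext(
        attribute=best,
        group_positions=group_positions,
        matched_origins=frozenset(matched_origins),
        groups_matched_anywhere=frozenset(groups_anywhere),
        matched_terms=frozenset(matched_terms),
        total_term_occurrences=total,
    )


def proximity_score(position_lists: Sequence[Sequence[int]]) -> float:
    """Closeness-and-order score of matched terms within one attribute.

    One matched term scores 1.0.  For m >= 2 terms the minimal token
    window containing at least one occurrence of each term is found;
    the base score is ``m / span`` (inclusive token span) and is
    multiplied by 0.8 when the terms do not appear in query order inside
    that window.  The result is clamped to [0, 1].
    """
    lists = [sorted(p) for p in position_lists if p]
    if not lists:
        raise ValueError("proximity_score requires at least one matched term")
    m = len(lists)
    if m == 1:
        return 1.0
    events = sorted(
        (pos, term_i) for term_i, positions in enumerate(lists) for pos in positions
    )
    best_span = None
    best_window: list[tuple[int, int]] | None = None
    count: Counter = Counter()
    left = 0
    for right, (pos, ti) in enumerate(events):
        count[ti] += 1
        while count[events[left][1]] > 1:
            count[events[left][1]] -= 1
            left += 1
        if len(count) == m:
            span = pos - events[left][0] + 1
            if best_span is None or span < best_span:
                best_span = span
                best_window = events[left : right + 1]
    assert best_span is not None and best_window is not None
    base = m / best_span
    # in-order check: earliest occurrence of each term inside the window
    firsts: dict[int, int] = {}
    for pos, ti in best_window:
        firsts.setdefault(ti, pos)
    ordered_positions = [firsts[ti] for ti in sorted(firsts)]
    in_order = all(a < b for a, b in zip(ordered_positions, ordered_positions[1:]))
    score = base if in_order else base * 0.8
    return max(0.0, min(1.0, score))


def keyword_context_score(
    matched_positions: Sequence[int],
    attribute_tokens: Sequence[str],
    config: FeatureConfig,
) -> float:
    """Good/bad keyword proximity: (1 + good - bad) / 2, in {0, 0.5, 1}."""
    w = config.keyword_window
    good = set(config.good_keywords)
    bad = set(config.bad_keywords)
    p = n = 0
    if matched_positions and (good or bad):
        for mp in matched_positions:
            lo, hi = max(0, mp - w), min(len(attribute_tokens), mp + w + 1)
            for tok in attribute_tokens[lo:hi]:
                if tok in good:
                    p = 1
                if tok in bad:
                    n = 1
            if p and n:
                break
    return (1 + p - n) / 2


def _phrase_in_tokens(phrase: Sequence[str], tokens: Sequence[str]) -> bool:
    k = len(phrase)
    if k == 0 or k > len(tokens):
        return False
    return any(tuple(tokens[i : i + k]) == tuple(phrase) for i in range(len(tokens) - k + 1))


def organism_match_score(
    query_tokens: Sequence[str], record: Record, config: FeatureConfig
) -> float:
    """1 when the query names the record's organism, 0 when it names a
    different one, 0.5 when either side is silent."""
    query_taxa = [
        g
        for g in config.taxonomy
        if any(_phrase_in_tokens(tokenize(alias), query_tokens) for alias in g)
    ]
    if not query_taxa or record.organism is None:
        return 0.5
    organism_tokens = tokenize(record.organism)
    for group in query_taxa:
        if any(_phrase_in_tokens(tokenize(alias), organism_tokens) for alias in group):
            return 1.0
    return 0.0


def sequence_length_score(length: int | None, config: FeatureConfig) -> float:
    if length is None:
        return 0.0
    return min(1.0, math.log10(1 + length) / math.log10(1 + config.length_cap))


def extract_features(
    query_spec: QuerySpec,
    record: Record,
    hit_context: HitContext,
    index: InvertedIndex,
    config: FeatureConfig,
) -> list[float]:
    """Compute the 11 feature values of one hit, each in [0, 1]."""
    rid = record.record_id
    attr = hit_context.attribute
    attribute_weight = (
        config.attribute_weights.get(attr, DEFAULT_WEIGHT)
        if attr is not None
        else DEFAULT_WEIGHT
    )
    database_weight = config.database_weights.get(record.source_db, DEFAULT_WEIGHT)

    total_tokens = index.record_token_counts.get(rid, 0)
    term_frequency = (
        min(1.0, hit_context.total_term_occurrences / total_tokens)
        if total_tokens
        else 0.0
    )

    if hit_context.group_positions:
        cooccurrence = proximity_score(
            [hit_context.group_positions[gi] for gi in sorted(hit_context.group_positions)]
        )
    else:
        cooccurrence = 0.0

    if attr is not None:
        attr_tokens = index.attribute_tokens(rid, attr)
        keyword_context = keyword_context_score(
            hit_context.matched_positions(), attr_tokens, config
        )
        attr_len = len(attr_tokens)
        coverage_positions = len(hit_context.matched_positions())
        text_position_coverage = coverage_positions / attr_len if attr_len else 0.0
    else:
        keyword_context = 0.5
        text_position_coverage = 0.0

    organism = organism_match_score(tokenize(query_spec.raw), record, config)
    seq_len_norm = sequence_length_score(record.sequence_length, config)

    # A hit that exists only through automatic synonym expansion is
    # down-flagged; direct (exact or user-corrected) matches score 1.
    if hit_context.matched_origins & {EXACT, CORRECTED}:
        synonym_origin = 1.0
    else:
        synonym_origin = 0.0

    n_groups = len(query_spec.groups)
    query_coverage = (
        len(hit_context.groups_matched_anywhere) / n_groups if n_groups else 0.0
    )

    N = index.n_records
    matched_known = [t for t in hit_context.matched_terms if t in index.df]
    if N > 1 and matched_known:
        log_n = math.log(N)
        idf_weight = sum(
            math.log(N / index.df[t]) / log_n for t in matched_known
        ) / len(matched_known)
    else:
        idf_weight = 0.0

    vector = [
        attribute_weight,
        database_weight,
        term_frequency,
        cooccurrence,
        keyword_context,
        organism,
        seq_len_norm,
        text_position_coverage,
        synonym_origin,
        query_coverage,
        min(1.0, max(0.0, idf_weight)),
    ]
    assert len(vector) == N_FEATURES
    return vector
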