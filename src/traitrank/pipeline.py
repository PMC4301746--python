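"""End-to-end search: expansion, retrieval, feature scoring, snippets, links.

Ties the index, query assistance, feature extractor, neural ranker and
annotation linker into one call.  Retrieval is disjunctive — a record
matching any query term group is a hit — and the hits are ordered by
the network's predicted relevance; the conjunctive expected-results
estimate is reported separately, as search engines display it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .annotations import AnnotationLink, MappingEntry, resolve_links
from .features import FeatureConfig, build_hit_context, extract_features
from .index import InvertedIndex, estimate_hits, tokenize
from .query import QuerySpec, SynonymTable, correct_spelling, expand_query
from .ranker import RankerNetwork, rank

DEFAULT_SNIPPET_RADIUS = 8


@dataclass
class Snippet:
    """A short excerpt of the matched attribute with highlight offsets."""

    attribute: str
    text: str
    # (start, end) character offsets of matched tokens within ``text``
    match_spans: tuple[tuple[int, int], ...]


@dataclass
class SearchResult:
    position: int  # 1-based rank
    record_id: str
    source_db: str
    score: float
    features: list[float]
    snippet: Snippet
    links: list[AnnotationLink] = field(default_factory=list)


@dataclass
class SearchResponse:
    query: str
    query_spec: QuerySpec
    estimated_hits: int
    spelling_suggestions: dict[str, list[str]]
    results: list[SearchResult]


def make_snippet(
    tokens: Sequence[str],
    matched_positions: Sequence[int],
    radius: int = DEFAULT_SNIPPET_RADIUS,
    attribute: str = "",
) -> Snippet:
    """Excerpt of ±``radius`` tokens around the first match cluster.

    Without matches the first ``2*radius + 1`` tokens are shown.
    Ellipses mark truncation on either side; match spans are character
    offsets into the returned excerpt text.
    """
    matched = sorted(p for p in matched_positions if 0 <= p < len(tokens))
    if matched:
        center = matched[0]
        lo, hi = max(0, center - radius), min(len(tokens), center + radius + 1)
    else:
        lo, hi = 0, min(len(tokens), 2 * radius + 1)
    window = tokens[lo:hi]
    prefix = "… " if lo > 0 else ""
    suffix = " …" if hi < len(tokens) else ""
    offsets: list[tuple[int, int]] = []
    cursor = len(prefix)
    starts = {}
    for i, tok in enumerate(window):
        starts[lo + i] = (cursor, cursor + len(tok))
        cursor += len(tok) + 1
    for p in matched:
        if p in starts:
            offsets.append(starts[p])
    text = prefix + " ".join(window) + suffix
    return Snippet(attribute=attribute, text=text, match_spans=tuple(offsets))


def search(
    index: InvertedIndex,
    query: str,
    network: RankerNetwork,
    feature_config: FeatureConfig,
    *,
    synonyms: SynonymTable | None = None,
    use_synonyms: bool = True,
    database: str | None = None,
    mappings: Sequence[MappingEntry] = (),
    top: int | None = None,
    snippet_radius: int = DEFAULT_SNIPPET_RADIUS,
) -> SearchResponse:
    """Run one query and return ranked, feature-scored results.

    ``database`` restricts hits to one source database; ``use_synonyms``
    toggles synonym expansion.  Spelling suggestions are reported, never
    silently applied.
    """
    spec = expand_query(query, synonyms, use_synonyms=use_synonyms)
    suggestions = {
        tok: correct_spelling(tok, index)
        for tok in tokenize(query)
        if tok not in index.df
    }
    candidates: set[str] = set()
    for group in spec.groups:
        for variant in group:
            candidates |= index.records_with_phrase(variant.tokens)
    if database is not None:
        candidates = {
            r for r in candidates if index.records[r].source_db == database
        }
    hits = []
    contexts = {}
    for rec_id in sorted(candidates):
        record = index.records[rec_id]
        ctx = build_hit_context(spec, record, index)
        if ctx.attribute is None:
            continue
        contexts[rec_id] = ctx
        hits.append(
            (rec_id, extract_features(spec, record, ctx, index, feature_config))
        )
    ranked = rank(network, hits)
    if top is not None:
        ranked = ranked[:top]

    corpus = index.records
    results = []
    for pos, (rec_id, score, feats) in enumerate(ranked, start=1):
        record = corpus[rec_id]
        ctx = contexts[rec_id]
        snippet = make_snippet(
            index.attribute_tokens(rec_id, ctx.attribute),
            ctx.matched_positions(),
            snippet_radius,
            attribute=ctx.attribute,
        )
        links = resolve_links(record, mappings, corpus) if mappings else []
        results.append(
            SearchResult(pos, rec_id, record.source_db, score, feats, snippet, links)
        )
    n_est = estimate_hits(spec, index)
    return SearchResponse(
        query=query,
        query_spec=spec,
        estimated_hits=n_est,
        spelling_suggestions=suggestions,
        results=results,
    )
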