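"""Tokenization, positional inverted index, and the TF-IDF/VSM baseline.

The index stores, for every term, per-record and per-attribute token
positions, so that proximity, coverage and snippet features can be
computed without rescanning the corpus.  The cosine vector-space ranker
defined here (weights ``tf * (1 + ln(N/df))``) is the comparison system
against which the neural ranker is evaluated.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .records import Record, read_records, write_records

_TOKEN_RE = re.compile(r"[0-9a-z]+")

#: Tokens shorter than this are discarded (keeps 2-letter gene symbols,
#: drops single digits/letters from accession punctuation).
MIN_TOKEN_LEN = 2

INDEX_FORMAT_VERSION = 1


def tokenize(text: str) -> list[str]:
    """Lowercase, split on non-alphanumerics, drop tokens shorter than 2.

    No stemming is applied; token order is preserved and the position of
    a token is its 0-based offset in the returned list.

    >>> tokenize("Sucrose synthase (EC 2.4.1.13)")
    ['sucrose', 'synthase', 'ec', '13']
    """
    return [t for t in _TOKEN_RE.findall(text.lower()) if len(t) >= MIN_TOKEN_LEN]


@dataclass(frozen=True)
class Posting:
    """Occurrences of one term in one attribute of one record."""

    term: str
    record_id: str
    attribute: str
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError("posting must carry at least one position")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("positions must be strictly ascending")


class InvertedIndex:
    """Positional inverted index over a corpus of :class:`Record` objects.

    Build with :func:`build_index`.  The corpus itself is retained so
    that feature extraction and snippet generation can reach attribute
    text without a separate store.
    """

    def __init__(self) -> None:
        self.records: dict[str, Record] = {}
        # term -> record_id -> attribute -> tuple of ascending positions
        self._postings: dict[str, dict[str, dict[str, tuple[int, ...]]]] = {}
        self.df: dict[str, int] = {}
        self.cf: dict[str, int] = {}
        self.record_token_counts: dict[str, int] = {}
        self.attribute_token_counts: dict[tuple[str, str], int] = {}
        # cached tokenized attributes: record_id -> attribute -> tokens
        self._tokens: dict[str, dict[str, list[str]]] = {}

    # -- construction --------------------------------------------------

    def add_record(self, record: Record) -> None:
        if record.record_id in self.records:
            raise ValueError(f"duplicate record_id: {record.record_id!r}")
        self.records[record.record_id] = record
        seen_terms: set[str] = set()
        total = 0
        tok_cache: dict[str, list[str]] = {}
        for attr, text in record.attributes.items():
            tokens = tokenize(text)
            tok_cache[attr] = tokens
            self.attribute_token_counts[(record.record_id, attr)] = len(tokens)
            total += len(tokens)
            positions: dict[str, list[int]] = {}
            for pos, tok in enumerate(tokens):
                positions.setdefault(tok, []).append(pos)
            for tok, pos_list in positions.items():
                by_rec = self._postings.setdefault(tok, {})
                by_attr = by_rec.setdefault(record.record_id, {})
                by_attr[attr] = tuple(pos_list)
                self.cf[tok] = self.cf.get(tok, 0) + len(pos_list)
                seen_terms.add(tok)
        for tok in seen_terms:
            self.df[tok] = self.df.get(tok, 0) + 1
        self.record_token_counts[record.record_id] = total
        self._tokens[record.record_id] = tok_cache

    # -- basic queries -------------------------------------------------

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def vocabulary(self) -> set[str]:
        return set(self.df)

    def postings(self, term: str) -> list[Posting]:
        out = []
        for rec_id, by_attr in self._postings.get(term, {}).items():
            for attr, positions in by_attr.items():
                out.append(Posting(term, rec_id, attr, positions))
        out.sort(key=lambda p: (p.record_id, p.attribute))
        return out

    def term_positions(self, term: str, record_id: str) -> dict[str, tuple[int, ...]]:
        """Positions of ``term`` per attribute of ``record_id``."""
        return dict(self._postings.get(term, {}).get(record_id, {}))

    def attribute_tokens(self, record_id: str, attribute: str) -> list[str]:
        return list(self._tokens[record_id][attribute])

    def term_count(self, term: str, record_id: str) -> int:
        """Total occurrences of ``term`` in the whole record."""
        by_attr = self._postings.get(term, {}).get(record_id, {})
        return sum(len(p) for p in by_attr.values())

    def phrase_positions(
        self, tokens: Sequence[str], record_id: str
    ) -> dict[str, list[int]]:
        """Start positions where ``tokens`` occur contiguously, per attribute.

        A single-token phrase degenerates to the term's own positions.
        """
        if not tokens:
            return {}
        first = self._postings.get(tokens[0], {}).get(record_id, {})
        out: dict[str, list[int]] = {}
        for attr, starts in first.items():
            hits = []
            for s in starts:
                ok = True
                for offset, tok in enumerate(tokens[1:], start=1):
                    pos = self._postings.get(tok, {}).get(record_id, {}).get(attr, ())
                    if s + offset not in pos:
                        ok = False
                        break
                if ok:
                    hits.append(s)
            if hits:
                out[attr] = hits
        return out

    def records_with_phrase(self, tokens: Sequence[str]) -> set[str]:
        if not tokens:
            return set()
        candidates = set(self._postings.get(tokens[0], {}))
        return {r for r in candidates if self.phrase_positions(tokens, r)}

    # -- TF-IDF vector space model ------------------------------------

    def idf(self, term: str) -> float:
        df = self.df.get(term)
        if not df:
            return 0.0
        return 1.0 + math.log(self.n_records / df)

    def record_vector(self, record_id: str) -> dict[str, float]:
        """TF-IDF weight per term of one record (whole-record tf)."""
        weights: dict[str, float] = {}
        for attr, tokens in self._tokens[record_id].items():
            for tok in tokens:
                weights[tok] = weights.get(tok, 0.0) + 1.0
        for tok in weights:
            weights[tok] *= self.idf(tok)
        return weights

    def record_norm(self, record_id: str) -> float:
        return math.sqrt(sum(w * w for w in self.record_vector(record_id).values()))

    # -- persistence ---------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Persist to a directory: versioned metadata plus the corpus.

        The index proper is rebuilt on load; at the corpus scales this
        package targets, a rebuild is cheaper than a custom postings
        serialization and keeps the on-disk format trivially stable.
        """
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {"format": "traitrank-index", "version": INDEX_FORMAT_VERSION,
                "n_records": self.n_records}
        (directory / "meta.json").write_text(
            json.dumps(meta, sort_keys=True) + "\n", encoding="utf-8"
        )
        ordered = [self.records[rid] for rid in sorted(self.records)]
        write_records(ordered, directory / "records.jsonl")

    @classmethod
    def load(cls, directory: str | Path) -> "InvertedIndex":
        directory = Path(directory)
        meta_path = directory / "meta.json"
        if not meta_path.exists():
            raise FileNotFoundError(f"not an index directory: {directory}")
        meta = json.loads(meta_path.read_text(encoding="utf-8"))
        if meta.get("version") != INDEX_FORMAT_VERSION:
            raise ValueError(
                f"unsupported index version {meta.get('version')!r}"
            )
        return build_index(read_records(directory / "records.jsonl"))


def build_index(records: Iterable[Record]) -> InvertedIndex:
    """Index a corpus; rejects duplicate record identifiers."""
    index = InvertedIndex()
    for rec in records:
        index.add_record(rec)
    return index


def tfidf_rank(
    query_terms: Sequence[str], index: InvertedIndex
) -> list[tuple[str, float]]:
    """Cosine vector-space ranking against the whole corpus.

    Document weights are ``tf * (1 + ln(N/df))``; the query carries unit
    weight per distinct term.  Records with score 0 are omitted; ties
    are broken by ascending record_id.
    """
    distinct = sorted(set(query_terms))
    known = [t for t in distinct if t in index.df]
    if not known or index.n_records == 0:
        return []
    q_norm = math.sqrt(len(distinct))
    scores: dict[str, float] = {}
    for term in known:
        idf = index.idf(term)
        for rec_id in index._postings.get(term, {}):
            tf = index.term_count(term, rec_id)
            scores[rec_id] = scores.get(rec_id, 0.0) + tf * idf
    ranked = []
    for rec_id, dot in scores.items():
        norm = index.record_norm(rec_id)
        if norm > 0 and dot > 0:
            ranked.append((rec_id, dot / (q_norm * norm)))
    ranked.sort(key=lambda x: (-x[1], x[0]))
    return ranked


def estimate_hits(query_spec, index: InvertedIndex) -> int:
    """Expected-results estimate: AND across term groups, OR within.

    Counts records containing, for every group of the expanded query,
    at least one member variant (synonym phrases match contiguously).
    """
    groups = getattr(query_spec, "groups", query_spec)
    if not groups:
        return 0
    result: set[str] | None = None
    for group in groups:
        members: set[str] = set()
        for variant in group:
            tokens = variant.tokens if hasattr(variant, "tokens") else tuple(variant)
            members |= index.records_with_phrase(tokens)
        result = members if result is None else (result & members)
        if not result:
            return 0
    return len(result) if result is not None else 0
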