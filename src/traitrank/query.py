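"""Query assistance: spelling correction, synonym expansion, related entries.

Expansion produces a :class:`QuerySpec`: an ordered list of term groups,
one per query token, where each group holds the token itself plus any
synonym phrases, each tagged with its origin (``exact``, ``synonym`` or
``corrected``).  Downstream feature extraction uses the origin tags to
flag hits produced purely by automatic synonym expansion.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .index import InvertedIndex, tokenize

EXACT = "exact"
SYNONYM = "synonym"
CORRECTED = "corrected"
_ORIGINS = (EXACT, SYNONYM, CORRECTED)


@dataclass(frozen=True)
class TermVariant:
    """One member of a query term group: a token sequence and its origin."""

    tokens: tuple[str, ...]
    origin: str = EXACT

    def __post_init__(self) -> None:
        if self.origin not in _ORIGINS:
            raise ValueError(f"origin must be one of {_ORIGINS}, got {self.origin!r}")
        if not self.tokens:
            raise ValueError("variant needs at least one token")


@dataclass(frozen=True)
class QuerySpec:
    """Expanded query: the raw string plus ordered groups of variants."""

    raw: str
    groups: tuple[tuple[TermVariant, ...], ...]

    def __post_init__(self) -> None:
        for group in self.groups:
            if not any(v.origin in (EXACT, CORRECTED) for v in group):
                raise ValueError("every group needs an exact or corrected member")


def damerau_levenshtein(a: str, b: str) -> int:
    """Edit distance counting insertions, deletions, substitutions and
    adjacent transpositions (optimal string alignment)."""
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    prev2: list[int] = []
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if (
                i > 1
                and j > 1
                and a[i - 1] == b[j - 2]
                and a[i - 2] == b[j - 1]
            ):
                cur[j] = min(cur[j], prev2[j - 2] + 1)
        prev2, prev = prev, cur
    return prev[lb]


def correct_spelling(term: str, index: InvertedIndex) -> list[str]:
    """Ranked spelling suggestions for a query term.

    Vocabulary candidates within Damerau-Levenshtein distance 1 (terms
    of length <= 4) or 2 (length >= 5), ranked by distance, then by
    descending collection frequency, then lexicographically.  A term
    already in the vocabulary yields no suggestions.  Suggestions are
    offered, never silently applied.
    """
    term = term.lower()
    if term in index.df:
        return []
    max_d = 1 if len(term) <= 4 else 2
    scored = []
    for cand in index.df:
        if abs(len(cand) - len(term)) > max_d:
            continue
        d = damerau_levenshtein(term, cand)
        if d <= max_d:
            scored.append((d, -index.cf[cand], cand))
    scored.sort()
    return [c for _, _, c in scored]


class SynonymTable:
    """Case-insensitive map from a term (or phrase) to synonym phrases."""

    def __init__(self, mapping: Mapping[str, Iterable[str]] | None = None) -> None:
        self._map: dict[str, set[str]] = {}
        if mapping:
            for term, syns in mapping.items():
                for syn in syns:
                    self.add(term, syn)

    def add(self, term: str, synonym: str) -> None:
        term_l, syn_l = term.lower().strip(), synonym.lower().strip()
        if not term_l or not syn_l or term_l == syn_l:
            return  # no self-synonyms
        self._map.setdefault(term_l, set()).add(syn_l)

    def lookup(self, term: str) -> set[str]:
        return set(self._map.get(term.lower(), ()))

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return {t: set(s) for t, s in self._map.items()}.items()

    # -- loading -------------------------------------------------------

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SynonymTable":
        """Two-column TSV: term <tab> synonym, one pair per line."""
        table = cls()
        with Path(path).open("r", encoding="utf-8") as fh:
            for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
                if not row or (len(row) == 1 and not row[0].strip()):
                    continue
                if row[0].startswith("#"):
                    continue
                if len(row) != 2:
                    raise ValueError(
                        f"line {lineno}: expected 2 tab-separated columns, got {len(row)}"
                    )
                table.add(row[0], row[1])
        return table

    @classmethod
    def from_obo(cls, path: str | Path) -> "SynonymTable":
        """Load term names and synonym lines from an OBO 1.2 flat file.

        Synonym scope tags (EXACT/BROAD/...) are ignored; every synonym
        string of a stanza becomes a synonym of the stanza's name.
        """
        import obonet

        graph = obonet.read_obo(str(path), ignore_obsolete=True)
        table = cls()
        for _, data in graph.nodes(data=True):
            name = data.get("name")
            if not name:
                continue
            for line in data.get("synonym", ()):
                # e.g. '"heat tolerance" EXACT []'
                if line.startswith('"') and '"' in line[1:]:
                    phrase = line[1 : line.index('"', 1)]
                else:
                    phrase = line
                table.add(name, phrase)
        return table


def expand_synonyms(tokens: Sequence[str], table: SynonymTable | None) -> QuerySpec:
    """One-level synonym expansion of tokenized query terms.

    Each token becomes a group containing itself (origin ``exact``) plus
    its table synonyms (origin ``synonym``); multi-word synonyms are kept
    as phrase variants.  No transitive closure is taken.
    """
    groups = []
    for tok in tokens:
        group = [TermVariant((tok,), EXACT)]
        if table is not None:
            for syn in sorted(table.lookup(tok)):
                syn_tokens = tuple(tokenize(syn))
                if syn_tokens and syn_tokens != (tok,):
                    group.append(TermVariant(syn_tokens, SYNONYM))
        groups.append(tuple(group))
    return QuerySpec(raw=" ".join(tokens), groups=tuple(groups))


def expand_query(
    query: str, table: SynonymTable | None = None, *, use_synonyms: bool = True
) -> QuerySpec:
    """Tokenize a raw query string and expand it into a :class:`QuerySpec`."""
    tokens = tokenize(query)
    spec = expand_synonyms(tokens, table if use_synonyms else None)
    return QuerySpec(raw=query, groups=spec.groups)


def suggest_related(record_id: str, index: InvertedIndex, k: int = 5) -> list[tuple[str, float]]:
    """Top-k related entries by TF-IDF cosine similarity of whole records.

    The record itself is excluded; ties are broken by ascending
    record_id.  Similarities lie in [0, 1].
    """
    if record_id not in index.records:
        raise KeyError(f"unknown record_id: {record_id!r}")
    if k < 1:
        raise ValueError("k must be >= 1")
    base = index.record_vector(record_id)
    base_norm = index.record_norm(record_id)
    sims = []
    for other in index.records:
        if other == record_id:
            continue
        vec = index.record_vector(other)
        dot = sum(w * vec.get(t, 0.0) for t, w in base.items())
        norm = index.record_norm(other)
        if base_norm > 0 and norm > 0 and dot > 0:
            sims.append((other, dot / (base_norm * norm)))
    sims.sort(key=lambda x: (-x[1], x[0]))
    return sims[:k]
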