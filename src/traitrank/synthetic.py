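"""Seeded generators for corpora with planted, class-graded relevance signal.

The generator builds a pseudo-word corpus in which, for each benchmark
query, records are drawn from the five relevance classes such that
higher classes receive

* a higher density of planted query terms,
* tighter, more often in-order term proximity,
* broader query-term coverage,
* a higher rate of organism agreement with the query,
* placement in higher-quality databases and attributes,
* longer sequences, and
* more good / fewer bad context keywords.

Signal therefore lives both in lexical features (visible to a TF-IDF
ranker) and in non-lexical features (organism, database, attribute,
length, keywords) that only the feature-based neural ranker can see.
Gold judgments (query, record, class) are emitted alongside the corpus.
All sampling is driven by a single seed.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .features import FeatureConfig
from .index import tokenize
from .query import SynonymTable
from .ranker import RELEVANCE_LABELS
from .records import Record
from .annotations import EVIDENCE_CLASSES, MappingEntry

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"

_GOOD_KEYWORDS = ("characterized", "validated", "reviewed")
_BAD_KEYWORDS = ("fragment", "putative", "uncharacterized")

_DATABASES = (
    "curated_proteins",
    "genome_annotations",
    "predicted_proteins",
    "community_notes",
)
_DATABASE_QUALITY = {
    "curated_proteins": 0.9,
    "genome_annotations": 0.7,
    "predicted_proteins": 0.4,
    "community_notes": 0.2,
}

_ATTRIBUTES = {"description": 12, "function": 25, "comment": 18}
_ATTRIBUTE_QUALITY = {"description": 0.9, "function": 0.6, "comment": 0.3}

_ORGANISMS = (
    "Hordeum vulgare",
    "Arabidopsis thaliana",
    "Oryza sativa",
    "Zea mays",
    "Triticum aestivum",
)
_TAXONOMY = (
    ("barley", "hordeum vulgare"),
    ("arabidopsis", "arabidopsis thaliana"),
    ("rice", "oryza sativa"),
    ("maize", "zea mays"),
    ("wheat", "triticum aestivum"),
)


def default_feature_config() -> FeatureConfig:
    """Feature configuration matched to the synthetic study conditions."""
    return FeatureConfig(
        attribute_weights=dict(_ATTRIBUTE_QUALITY),
        database_weights=dict(_DATABASE_QUALITY),
        good_keywords=_GOOD_KEYWORDS,
        bad_keywords=_BAD_KEYWORDS,
        keyword_window=5,
        length_cap=100_000,
        taxonomy=_TAXONOMY,
    )


def pseudo_vocabulary(size: int) -> list[str]:
    """Deterministic pseudo-word vocabulary of consonant-vowel syllables.

    Words are three CV syllables (e.g. ``"badofu"``), which cannot
    collide with natural-language query terms unless deliberately
    planted.
    """
    syllables = ["".join(p) for p in itertools.product(_CONSONANTS, _VOWELS)]
    words = []
    for combo in itertools.product(syllables, repeat=3):
        words.append("".join(combo))
        if len(words) >= size:
            return words
    raise ValueError(f"cannot build a vocabulary of size {size}")


@dataclass(frozen=True)
class Judgment:
    """A graded relevance judgment: query, record and one of 5 classes."""

    query: str
    record_id: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in RELEVANCE_LABELS:
            raise ValueError(f"unknown relevance label {self.label!r}")


@dataclass
class CorpusSpec:
    """Study conditions of the synthetic corpus.

    Per-class tuples are indexed by relevance class 0 ("no relevance")
    through 4 ("fully agree").
    """

    n_records: int = 1000
    noise_fraction: float = 0.2
    vocab_size: int = 400
    databases: tuple[str, ...] = _DATABASES
    attribute_lengths: dict[str, int] = field(
        default_factory=lambda: dict(_ATTRIBUTES)
    )
    organisms: tuple[str, ...] = _ORGANISMS
    class_mixture: tuple[float, ...] = (0.30, 0.20, 0.20, 0.15, 0.15)
    term_density: tuple[float, ...] = (0.02, 0.05, 0.08, 0.11, 0.15)
    proximity_tightness: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)
    coverage_fraction: tuple[float, ...] = (0.35, 0.5, 0.7, 0.85, 1.0)
    organism_agreement: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)
    good_keyword_prob: tuple[float, ...] = (0.05, 0.2, 0.4, 0.6, 0.8)
    bad_keyword_prob: tuple[float, ...] = (0.6, 0.45, 0.3, 0.15, 0.05)
    log10_length_mean: tuple[float, ...] = (1.8, 2.2, 2.6, 3.0, 3.4)
    log10_length_sd: float = 0.3
    length_present_prob: float = 0.85
    cross_ref_prob: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 1 or self.vocab_size < 1:
            raise ValueError("n_records and vocab_size must be >= 1")
        if abs(sum(self.class_mixture) - 1.0) > 1e-9:
            raise ValueError("class_mixture must sum to 1")
        for name in (
            "class_mixture",
            "term_density",
            "proximity_tightness",
            "coverage_fraction",
            "organism_agreement",
            "good_keyword_prob",
            "bad_keyword_prob",
        ):
            values = getattr(self, name)
            if len(values) != len(RELEVANCE_LABELS):
                raise ValueError(f"{name} needs {len(RELEVANCE_LABELS)} entries")
            if any(not 0.0 <= v <= 1.0 for v in values):
                raise ValueError(f"{name} entries must lie in [0, 1]")
        if not 0.0 <= self.noise_fraction < 1.0:
            raise ValueError("noise_fraction must lie in [0, 1)")


def _query_organism(query: str, organisms: Sequence[str]) -> str | None:
    tokens = tokenize(query)
    text = " ".join(tokens)
    for group, organism in zip(_TAXONOMY, organisms):
        for alias in group:
            alias_tokens = tokenize(alias)
            k = len(alias_tokens)
            if any(tokens[i : i + k] == alias_tokens for i in range(len(tokens) - k + 1)):
                return organism
    return None


def _quality_probs(qualities: Sequence[float], cls: int) -> np.ndarray:
    """Class-tilted categorical distribution over quality-scored choices."""
    alpha = 1.5 * (cls - 2)  # class 0 favors low quality, class 4 high
    w = np.exp(alpha * (np.asarray(qualities) - 0.5) * 2)
    return w / w.sum()


def generate_corpus(
    spec: CorpusSpec, queries: Sequence[str]
) -> tuple[list[Record], list[Judgment]]:
    """Generate a corpus with planted per-class relevance signal.

    Each non-noise record is tied to one query (round-robin over
    ``queries``) and one relevance class (drawn from the class mixture);
    the record's text, organism, database, sequence length and keyword
    context are planted according to the class's configured means.
    Returns the records and the gold judgments.  Deterministic per
    ``spec.seed``.
    """
    if not queries:
        raise ValueError("at least one query is required")
    rng = np.random.default_rng(spec.seed)
    vocab = pseudo_vocabulary(spec.vocab_size)
    n_classes = len(RELEVANCE_LABELS)
    n_noise = round(spec.n_records * spec.noise_fraction)
    n_assigned = spec.n_records - n_noise
    width = len(str(spec.n_records))
    record_ids = [f"rec{i:0{width}d}" for i in range(spec.n_records)]

    attr_names = list(spec.attribute_lengths)
    attr_quality = [_ATTRIBUTE_QUALITY.get(a, 0.5) for a in attr_names]
    db_quality = [_DATABASE_QUALITY.get(d, 0.5) for d in spec.databases]

    records: list[Record] = []
    judgments: list[Judgment] = []
    for i in range(spec.n_records):
        assigned = i < n_assigned
        query = queries[i % len(queries)] if assigned else None
        cls = int(rng.choice(n_classes, p=spec.class_mixture)) if assigned else 0

        # base pseudo-word text per attribute
        attr_tokens: dict[str, list[str]] = {}
        for name, mean_len in spec.attribute_lengths.items():
            length = max(4, int(rng.poisson(mean_len)))
            attr_tokens[name] = [vocab[j] for j in rng.integers(0, len(vocab), length)]

        organism: str | None
        if assigned:
            q_org = _query_organism(query, spec.organisms)
            if q_org is not None:
                if rng.random() < spec.organism_agreement[cls]:
                    organism = q_org
                elif rng.random() < 0.15:
                    organism = None
                else:
                    others = [o for o in spec.organisms if o != q_org]
                    organism = others[rng.integers(0, len(others))]
            else:
                organism = (
                    spec.organisms[rng.integers(0, len(spec.organisms))]
                    if rng.random() < 0.7
                    else None
                )
            source_db = spec.databases[
                rng.choice(len(spec.databases), p=_quality_probs(db_quality, cls))
            ]
            if rng.random() < spec.length_present_prob:
                log_len = rng.normal(spec.log10_length_mean[cls], spec.log10_length_sd)
                sequence_length = max(1, int(round(10**log_len)))
            else:
                sequence_length = None

            # plant query terms
            q_tokens = tokenize(query)
            m = len(q_tokens)
            target_attr = attr_names[
                rng.choice(len(attr_names), p=_quality_probs(attr_quality, cls))
            ]
            tokens = attr_tokens[target_attr]
            planted_positions: list[int] = []
            total_tokens = sum(len(v) for v in attr_tokens.values())
            if cls == 0:
                # non-relevant results still mention query terms (that is
                # why they were retrieved): a Poisson count around the
                # class-0 density, overlapping the low relevant classes
                k0 = int(rng.poisson(spec.term_density[0] * total_tokens))
                for pos in rng.permutation(len(tokens))[:k0]:
                    tokens[pos] = q_tokens[rng.integers(0, m)]
                    planted_positions.append(int(pos))
            else:
                n_distinct = max(1, int(round(m * spec.coverage_fraction[cls])))
                chosen = q_tokens[:n_distinct]
                # density is relative to the whole record's token count
                k_total = max(
                    n_distinct,
                    int(rng.poisson(spec.term_density[cls] * total_tokens)),
                )
                if len(tokens) < k_total + 4:
                    tokens.extend(
                        vocab[j]
                        for j in rng.integers(0, len(vocab), k_total + 4 - len(tokens))
                    )
                if rng.random() < spec.proximity_tightness[cls]:
                    start = int(rng.integers(0, len(tokens) - n_distinct + 1))
                    for off, qt in enumerate(chosen):
                        tokens[start + off] = qt
                        planted_positions.append(start + off)
                    extra = k_total - n_distinct
                    free = [p for p in range(len(tokens)) if p not in planted_positions]
                    for p in rng.permutation(free)[:extra]:
                        tokens[p] = chosen[rng.integers(0, n_distinct)]
                        planted_positions.append(int(p))
                else:
                    positions = rng.permutation(len(tokens))[:k_total]
                    for j, p in enumerate(positions):
                        tokens[p] = chosen[j % n_distinct]
                        planted_positions.append(int(p))
            # keyword context near a planted position
            if planted_positions:
                if rng.random() < spec.good_keyword_prob[cls]:
                    p = planted_positions[rng.integers(0, len(planted_positions))]
                    q = min(len(tokens) - 1, p + 1 + int(rng.integers(0, 3)))
                    if q not in planted_positions:
                        tokens[q] = _GOOD_KEYWORDS[rng.integers(0, len(_GOOD_KEYWORDS))]
                if rng.random() < spec.bad_keyword_prob[cls]:
                    p = planted_positions[rng.integers(0, len(planted_positions))]
                    q = max(0, p - 1 - int(rng.integers(0, 3)))
                    if q not in planted_positions:
                        tokens[q] = _BAD_KEYWORDS[rng.integers(0, len(_BAD_KEYWORDS))]
            judgments.append(
                Judgment(query, record_ids[i], RELEVANCE_LABELS[cls])
            )
        else:
            organism = (
                spec.organisms[rng.integers(0, len(spec.organisms))]
                if rng.random() < 0.5
                else None
            )
            source_db = spec.databases[rng.integers(0, len(spec.databases))]
            sequence_length = None

        records.append(
            Record(
                record_id=record_ids[i],
                source_db=source_db,
                attributes={name: " ".join(tok) for name, tok in attr_tokens.items()},
                organism=organism,
                sequence_length=sequence_length,
            )
        )

    # one-hop cross-references for annotation linking
    with_refs = []
    for rec in records:
        if rng.random() < spec.cross_ref_prob:
            n_refs = int(rng.integers(1, 3))
            choices = rng.choice(spec.n_records, size=n_refs, replace=False)
            refs = tuple(
                record_ids[c] for c in sorted(choices) if record_ids[c] != rec.record_id
            )
            rec = Record(
                rec.record_id,
                rec.source_db,
                rec.attributes,
                rec.organism,
                rec.sequence_length,
                refs,
            )
        with_refs.append(rec)
    return with_refs, judgments


def generate_mappings(
    records: Sequence[Record],
    seed: int,
    evidence_probs: dict[str, float] | None = None,
) -> list[MappingEntry]:
    """Assign 0-3 gene links per record with the given evidence mix."""
    evidence_probs = evidence_probs or {"HC": 0.4, "LC": 0.35, "NA": 0.25}
    probs = [evidence_probs.get(ev, 0.0) for ev in EVIDENCE_CLASSES]
    if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
        raise ValueError(
            f"evidence_probs must be a distribution over {EVIDENCE_CLASSES}"
        )
    rng = np.random.default_rng(seed)
    entries = []
    gene_counter = 0
    for rec in records:
        for _ in range(int(rng.integers(0, 4))):
            evidence = EVIDENCE_CLASSES[rng.choice(len(EVIDENCE_CLASSES), p=probs)]
            entries.append(
                MappingEntry(f"gene{gene_counter:06d}", rec.record_id, evidence)
            )
            gene_counter += 1
    return entries


def generate_synonym_table(
    vocabulary: Iterable[str], seed: int, rate: float
) -> SynonymTable:
    """Give each term a pseudo-word synonym with probability ``rate``.

    Synonyms are marked pseudo-words absent from the vocabulary, so a
    hit produced only by synonym expansion is detectable downstream.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    table = SynonymTable()
    for term in sorted(set(vocabulary)):
        if rng.random() < rate:
            table.add(term, "zz" + term)
    return table


# -- plain-text writers/readers for the generated artifacts -----------

def write_judgments(judgments: Iterable[Judgment], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["query", "record_id", "label"])
        for j in judgments:
            writer.writerow([j.query, j.record_id, j.label])


def read_judgments(path: str | Path) -> list[Judgment]:
    out = []
    with Path(path).open("r", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(Judgment(row["query"], row["record_id"], row["label"]))
    return out


def write_synonyms_tsv(table: SynonymTable, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for term, syns in sorted(table.items()):
            for syn in sorted(syns):
                writer.writerow([term, syn])


def write_synonyms_obo(table: SynonymTable, path: str | Path) -> None:
    """Write the table as a minimal OBO 1.2 flat file."""
    lines = ["format-version: 1.2", ""]
    for i, (term, syns) in enumerate(sorted(table.items()), start=1):
        lines.append("[Term]")
        lines.append(f"id: TR:{i:07d}")
        lines.append(f"name: {term}")
        for syn in sorted(syns):
            lines.append(f'synonym: "{syn}" EXACT []')
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
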