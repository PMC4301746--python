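"""Graded-relevance evaluation: benchmark queries, judgment sampling,
per-class score distributions and neural-vs-TF-IDF class separation.

The benchmark is a fixed set of 20 trait-oriented keyword queries
(stress response, agronomic traits, gene names, taxonomy, metabolic and
regulatory function) shipped as an in-repo fixture.  Judged results fall
into five ordered relevance classes; separation between the
"no relevance" class and the rest is measured as the Mann-Whitney AUC —
the probability that a randomly chosen relevant item outscores a
randomly chosen non-relevant one, ties counting one half.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .features import extract_features, build_hit_context, FeatureConfig
from .index import InvertedIndex, build_index, tfidf_rank, tokenize
from .query import expand_query
from .ranker import (
    RELEVANCE_LABELS,
    RankerNetwork,
    TrainingConfig,
    init_network,
    label_to_target,
    train,
)
from .synthetic import (
    CorpusSpec,
    Judgment,
    default_feature_config,
    generate_corpus,
)

DEFAULT_JUDGMENT_QUOTA = 20


@dataclass(frozen=True)
class BenchmarkQuery:
    query_class: str
    subquery_class: str
    query: str

    def __post_init__(self) -> None:
        if not (self.query_class and self.subquery_class and self.query):
            raise ValueError("benchmark query fields must be non-empty")


def load_benchmark() -> list[BenchmarkQuery]:
    """The 20 benchmark trait queries shipped with the package."""
    path = resources.files("traitrank.data") / "benchmark_queries.tsv"
    out: list[BenchmarkQuery] = []
    with path.open("r", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(
                BenchmarkQuery(
                    row["query_class"], row["subquery_class"], row["query"]
                )
            )
    if len(out) != 20:
        raise ValueError(f"benchmark fixture corrupt: expected 20 queries, got {len(out)}")
    return out


def sample_for_judgment(
    results_per_query: Mapping[str, Sequence[str]],
    quota: int = DEFAULT_JUDGMENT_QUOTA,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Randomly draw up to ``quota`` result records per query for judging.

    Sampling is uniform without replacement and deterministic per seed.
    """
    if quota < 1:
        raise ValueError("quota must be >= 1")
    rng = np.random.default_rng(seed)
    pairs: list[tuple[str, str]] = []
    for query in results_per_query:  # preserve caller's query order
        records = list(results_per_query[query])
        n = min(quota, len(records))
        if n == 0:
            continue
        chosen = rng.choice(len(records), size=n, replace=False)
        pairs.extend((query, records[i]) for i in sorted(chosen))
    return pairs


def _five_number(values: Sequence[float]) -> dict[str, float]:
    arr = np.asarray(values, dtype=float)
    q = np.quantile(arr, [0.0, 0.25, 0.5, 0.75, 1.0])
    return {"min": float(q[0]), "q1": float(q[1]), "median": float(q[2]),
            "q3": float(q[3]), "max": float(q[4])}


@dataclass
class EvalReport:
    """Per-class score summaries and separation statistics per ranker."""

    # ranker -> class label -> five-number summary (None if class empty)
    class_summaries: dict[str, dict[str, dict[str, float] | None]]
    # ranker -> AUC of "no relevance" vs all other classes
    separation: dict[str, float]
    n_judgments: int = 0
    metadata: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "class_summaries": self.class_summaries,
                "separation": self.separation,
                "n_judgments": self.n_judgments,
                "metadata": self.metadata,
            },
            sort_keys=True,
            indent=2,
        )

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n", encoding="utf-8")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ranker, per_class in sorted(self.class_summaries.items()):
            for label in RELEVANCE_LABELS:
                summary = per_class.get(label)
                row = {"ranker": ranker, "class": label}
                if summary is None:
                    row.update({k: np.nan for k in ("min", "q1", "median", "q3", "max")})
                    row["n"] = 0
                else:
                    row.update(summary)
                rows.append(row)
        return pd.DataFrame(rows)

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def score_distributions(
    judgments: Sequence[Judgment],
    scores_per_ranker: Mapping[str, Mapping[tuple[str, str], float]],
) -> EvalReport:
    """Five-number summaries per relevance class per ranker.

    Every judged (query, record) pair must have a score from every
    ranker; classes with no judgments are reported as empty, not zero.
    """
    summaries: dict[str, dict[str, dict[str, float] | None]] = {}
    auc: dict[str, float] = {}
    for ranker, scores in scores_per_ranker.items():
        by_class: dict[str, list[float]] = {label: [] for label in RELEVANCE_LABELS}
        for j in judgments:
            key = (j.query, j.record_id)
            if key not in scores:
                raise KeyError(
                    f"ranker {ranker!r} has no score for judged pair {key!r}"
                )
            by_class[j.label].append(scores[key])
        summaries[ranker] = {
            label: (_five_number(vals) if vals else None)
            for label, vals in by_class.items()
        }
        non_relevant = by_class[RELEVANCE_LABELS[0]]
        relevant = [v for label in RELEVANCE_LABELS[1:] for v in by_class[label]]
        if non_relevant and relevant:
            auc[ranker] = separation_auc_from_scores(non_relevant, relevant)
    return EvalReport(
        class_summaries=summaries, separation=auc, n_judgments=len(judgments)
    )


def separation_auc_from_scores(
    non_relevant: Sequence[float], relevant: Sequence[float]
) -> float:
    """Mann-Whitney AUC: P(relevant score > non-relevant score) + P(tie)/2."""
    if len(non_relevant) == 0 or len(relevant) == 0:
        raise ValueError("both score sets must be non-empty")
    u = mannwhitneyu(relevant, non_relevant, alternative="two-sided").statistic
    return float(u / (len(relevant) * len(non_relevant)))


def separation_auc(
    judgments: Sequence[Judgment], scores: Mapping[tuple[str, str], float]
) -> float:
    """AUC of the "no relevance" class against the union of the rest."""
    non_relevant, relevant = [], []
    for j in judgments:
        value = scores[(j.query, j.record_id)]
        (non_relevant if j.label == RELEVANCE_LABELS[0] else relevant).append(value)
    return separation_auc_from_scores(non_relevant, relevant)


# -- the class-separation experiment ----------------------------------

@dataclass
class ExperimentResult:
    report: EvalReport
    neural_auc: float
    tfidf_auc: float
    n_train: int
    n_judged: int

    @property
    def neural_medians(self) -> list[float | None]:
        per_class = self.report.class_summaries["neural"]
        return [
            (per_class[label]["median"] if per_class[label] else None)
            for label in RELEVANCE_LABELS
        ]


def run_separation_experiment(
    seed: int,
    spec: CorpusSpec | None = None,
    queries: Sequence[str] | None = None,
    feature_config: FeatureConfig | None = None,
    training: TrainingConfig | None = None,
    quota: int = DEFAULT_JUDGMENT_QUOTA,
) -> ExperimentResult:
    """Generate a graded corpus, train the ranker, compare it to TF-IDF.

    Protocol: records planted for each benchmark query are that query's
    result elements; ``quota`` of them are sampled for the judgment set
    and the remainder form the training feedback.  Both rankers score
    every judged pair (a record a ranker does not retrieve scores 0 for
    TF-IDF); separation AUC and per-class distributions are reported.
    Deterministic per ``seed``.
    """
    if queries is None:
        queries = [bq.query for bq in load_benchmark()]
    spec = spec or CorpusSpec(seed=seed)
    feature_config = feature_config or default_feature_config()
    training = training or TrainingConfig(seed=seed)

    records, gold = generate_corpus(spec, queries)
    index = build_index(records)
    gold_by_pair = {(j.query, j.record_id): j for j in gold}
    results_per_query: dict[str, list[str]] = {q: [] for q in queries}
    for j in gold:
        results_per_query[j.query].append(j.record_id)

    judged_pairs = set(sample_for_judgment(results_per_query, quota, seed))
    test_judgments = [gold_by_pair[p] for p in gold_by_pair if p in judged_pairs]
    train_judgments = [gold_by_pair[p] for p in gold_by_pair if p not in judged_pairs]

    specs = {q: expand_query(q) for q in queries}
    feature_cache: dict[tuple[str, str], list[float]] = {}

    def features_for(query: str, record_id: str) -> list[float]:
        key = (query, record_id)
        if key not in feature_cache:
            record = index.records[record_id]
            ctx = build_hit_context(specs[query], record, index)
            feature_cache[key] = extract_features(
                specs[query], record, ctx, index, feature_config
            )
        return feature_cache[key]

    examples = [
        (features_for(j.query, j.record_id), label_to_target(j.label))
        for j in train_judgments
    ]
    network = train(init_network(training.seed), examples, training)

    tfidf_scores_by_query = {q: dict(tfidf_rank(tokenize(q), index)) for q in queries}
    neural_scores: dict[tuple[str, str], float] = {}
    tfidf_scores: dict[tuple[str, str], float] = {}
    for j in test_judgments:
        key = (j.query, j.record_id)
        neural_scores[key] = network.predict(features_for(*key))
        tfidf_scores[key] = tfidf_scores_by_query[j.query].get(j.record_id, 0.0)

    report = score_distributions(
        test_judgments, {"neural": neural_scores, "tfidf": tfidf_scores}
    )
    report.metadata = {
        "seed": seed,
        "n_records": spec.n_records,
        "quota": quota,
        "epochs": training.epochs,
        "learning_rate": training.learning_rate,
    }
    return ExperimentResult(
        report=report,
        neural_auc=report.separation["neural"],
        tfidf_auc=report.separation["tfidf"],
        n_train=len(examples),
        n_judged=len(test_judgments),
    )
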