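# Methods

## Scope and design

`traitrank` is a library-first implementation of feature-based,
learned relevance ranking over corpora of multi-attribute biological
annotation records, with a thin command-line wrapper. The public
surface is the importable API (`traitrank.*`) plus narrative scripts
under `examples/`; the CLI exposes the same operations
(`index`, `search`, `train`, `feedback`, `evaluate`, `simulate`,
`export`) for shell use without adding behaviour of its own.

## Tokenization and indexing

Text is lowercased and split on every non-alphanumeric character;
tokens shorter than two characters are discarded, and no stemming is
applied. This keeps short gene symbols (`wus`, `ec`) intact while
dropping the single digits produced by accession punctuation
(`EC 2.4.1.13` → `ec`, `13`). Token positions are 0-based offsets in
the filtered token list of one attribute; each attribute is indexed
independently so per-attribute features (coverage, proximity,
snippets) are computable. The index keeps document frequency,
collection frequency, per-record and per-attribute token counts, and
per-attribute positional postings. Persistence stores a versioned
metadata file plus the corpus as sorted JSON-lines; the postings are
rebuilt on load, which at the corpus sizes this package targets is
cheaper and more robust than a custom postings serialization.

## TF–IDF baseline

The comparison ranker is a classic cosine vector-space model with
document weights `tf(t,d) · (1 + ln(N/df(t)))` and unit query weights
per distinct term, `tf` taken over the whole record. Records with zero
score are omitted; all ties anywhere in the package break by ascending
record identifier, for reproducibility. A useful consequence of this
weighting, exploited by a property test: duplicating the entire corpus
leaves every score unchanged (every `N/df` ratio is preserved), whereas
adding any single document perturbs all IDF values.

## Query assistance

Spelling suggestion uses Damerau–Levenshtein distance in the optimal
string alignment variant (insertions, deletions, substitutions,
adjacent transpositions) — transpositions dominate typos in biological
terms. Candidates must lie within distance 1 for query terms of up to
4 characters, distance 2 from 5 characters, and are ranked by distance,
then collection frequency, then lexicographically. Suggestions are
displayed, never silently applied; a user-accepted suggestion enters
the query with origin `corrected`.

Synonym expansion is one-level (no transitive closure): each query
token becomes a group holding itself (`exact`) plus its table synonyms
(`synonym`), with multi-word synonyms kept as contiguous phrases.
Tables load from two-column TSV or OBO 1.2 flat files (via `obonet`;
synonym scope tags are ignored). Related entries are the top-k records
by TF–IDF cosine similarity to a given record, self excluded.

Retrieval for the ranked result list is disjunctive — any record
matching at least one term group is a hit, so partially matching
records can still surface — while the "expected results" estimate uses
conjunctive semantics (every group must match, any member within a
group), mirroring how search engines display an AND-query count next
to a more forgiving ranked list.

## The 11 relevance features

All features are normalized to [0, 1]; the fixed order is
`attribute_weight, database_weight, term_frequency, cooccurrence,
keyword_context, organism_match, sequence_length_norm,
text_position_coverage, synonym_origin, query_coverage, idf_weight`.

* **attribute_weight / database_weight** — configured lookup maps
  (default 0.5 when unmapped). Scalar encodings keep the input layer at
  11 neurons; a one-hot encoding would tie the architecture to the
  corpus schema.
* **term_frequency** — total occurrences of matched query terms across
  the whole record divided by the record's token count (bounded by
  construction; the normalized form is chosen so the feature cannot
  grow with entry length).
* **cooccurrence** — for one matched term group, 1.0; otherwise the
  minimal token window containing at least one occurrence of each
  matched group gives base `m / span`, multiplied by 0.8 when the
  groups' earliest in-window occurrences are not in query order.
* **keyword_context** — `(1 + good − bad)/2` where `good`/`bad`
  indicate a configured good/bad keyword within ±5 tokens (default
  window) of any match; empty lists give the neutral 0.5.
* **organism_match** — the taxonomy configuration is a list of alias
  groups (`barley` ↔ `Hordeum vulgare`); 1 if the query names the
  record's organism, 0 if it names a different one, 0.5 if either side
  is silent. Detection is list-based only; no named-entity recognition.
* **sequence_length_norm** — `min(1, log10(1+len)/log10(1+Lmax))` with
  `Lmax` = 100 000 residues/bases by default (longer than any plant
  protein, within genomic-contig range); absent lengths score 0.
* **text_position_coverage** — distinct matched token positions divided
  by the matched attribute's token count. The "matched attribute" is
  the one matching the most distinct groups (ties: most matched
  positions, then attribute order).
* **synonym_origin** — 0 only when the hit exists purely through
  automatic synonym expansion; exact or user-corrected matches score 1.
  Synonym-only hits carry weaker evidence and can be filtered.
* **query_coverage** and **idf_weight** — fraction of query term groups
  matched anywhere in the record, and the mean `ln(N/df)/ln(N)` of
  matched terms (0 for N ≤ 1). The named feature model has nine
  properties but the ranker input is stated as 11-dimensional; these
  two standard IR signals complete the dimensionality and are explicit,
  swappable extensions.

A record with no match at all gets zeros for the lexical features,
neutral 0.5 for the categorical ones, and its ordinary database /
organism / length values — such records still receive scores when they
appear in a judgment set.

## Neural ranker and training

Architecture 11→16→8→1 with sigmoid activations at every layer
(output therefore strictly inside (0,1)). Weights initialize uniformly
from [−0.5, 0.5] under a seeded generator. Training is full-batch
gradient descent on MSE via backpropagation; learning rate 0.5 and
2000 epochs by default — small enough to stay stable on [0,1]-bounded
features, large enough to fit a few hundred graded judgments to
MSE < 0.01 in about a second. The original system's loss, optimizer
and initialization are not publicly specified; these choices favour
determinism and testability, and all are configurable. Gradient
correctness is the module's core oracle: backprop is checked against
central differences (h = 1e−5) to a relative error below 1e−6.

The five feedback classes map to equally spaced targets on [0, 1],
preserving the class order; nothing in the data dictates unequal
spacing. Feedback is stored as an append-only TSV
(profile, query, record_id, label, timestamp); retraining is explicit,
one network per named profile, persisted as a single JSON document.

## Annotation linking

Mapping files are 3-column TSV (gene_id, record_id, evidence) with
blank evidence meaning NA, rendered "N/A". Links are *direct* when the
mapping names the hit record and *indirect* when it names one of the
hit's cross-references — exactly one hop, bounding both cost and
semantic drift. Ordering is direct before indirect, then evidence
HC > LC > NA, then gene identifier; the sort is total, so output is
invariant to mapping-file order.

## Evaluation protocol

The benchmark fixture holds 20 trait-oriented keyword queries in six
query classes (trait, biological entity, taxonomy, affiliation,
metabolic function, regulatory function). For each query, 20 result
elements are sampled uniformly without replacement for judgment — the
per-query quota is fixed at 20 so the full protocol yields 400
judgments. Judged scores are summarized per relevance class as
five-number summaries (linear-interpolation quantiles), and separation
is measured as the Mann–Whitney AUC of "no relevance" against the
union of the other four classes (ties count ½) — threshold-free and
checkable against pairwise enumeration.

In the packaged experiment (`run_separation_experiment`), each query's
result-element universe is the set of records the generator tied to
that query; the sampled 400 pairs form the held-out judgment set and
the unsampled gold pairs (about 400) serve as training feedback. The
TF–IDF baseline scores a judged pair it does not retrieve as 0. AUC is
pooled over queries for both rankers alike.

## Synthetic study conditions

The generator builds 1000 records by default: 80 % tied round-robin to
the benchmark queries (≈ 40 per query), 20 % background noise; three
attributes (description/function/comment, mean lengths 12/25/18
tokens) filled from a 400-word consonant-vowel pseudo-vocabulary that
cannot collide with natural-language query terms; four databases and
five plant organisms. Per relevance class 0–4 the planted conditions
are:

| signal | class 0 → 4 |
| --- | --- |
| query-term density (fraction of record tokens) | 0.02, 0.05, 0.08, 0.11, 0.15 |
| in-order adjacent placement probability | 0.1, 0.3, 0.5, 0.7, 0.9 |
| distinct-term coverage fraction | 0.35, 0.5, 0.7, 0.85, 1.0 |
| organism agreement with the query | 0.1, 0.3, 0.5, 0.7, 0.9 |
| good-keyword / bad-keyword probability | 0.05→0.8 / 0.6→0.05 |
| mean log10 sequence length | 1.8, 2.2, 2.6, 3.0, 3.4 |

with class mixture (0.30, 0.20, 0.20, 0.15, 0.15) and class-tilted
database/attribute placement. Planted occurrence counts are Poisson
around the class mean — non-relevant results still mention query terms
(that is why they were retrieved), so adjacent classes overlap
lexically, as real judgment sets do. Because organism, database,
attribute, keyword and length signal is invisible to term statistics,
the feature-based ranker separates classes better than the TF–IDF
baseline under these conditions; that comparison is the package's
qualitative headline result, reproduced at desk scale (1000 records,
seeds 1–5, about a second per seed) by the acceptance tests.

What the generator does *not* emulate: real annotation prose and its
topical correlations, skewed natural-language term distributions,
cross-query relevance (a record planted for one query is never judged
against another), database-scale corpora, or human labelling noise.
Passing tests therefore demonstrate correctness of the machinery and
the constructibility of the learned ranker's advantage — not its
magnitude on live databases.

## Numerical choices and degenerate inputs

Quantiles use linear interpolation between order statistics. The AUC
uses the exact Mann–Whitney U statistic. Sigmoid evaluation is split
by sign to avoid overflow. Empty queries estimate 0 hits and return no
results; empty training sets return the network unchanged; an empty
judgment class is reported as empty rather than zero. Unknown query
terms contribute nothing to TF–IDF scores. Duplicate record
identifiers are rejected at indexing with the identifier named. Seeds
propagate explicitly; every generator is `numpy.random.default_rng`
and identical seeds give byte-identical indices, networks, rankings
and reports.

## Known limitations

* Snippets are rebuilt from the filtered token stream, so punctuation
  and sub-2-character tokens of the original text do not appear in
  excerpts.
* Spelling correction scans the vocabulary linearly per query term;
  adequate up to ~10⁵ terms, but a production system would use a
  bk-tree or n-gram prefilter.
* The feature extractor scores one (query, record) pair at a time;
  there is no cross-record normalization such as BM25 saturation.
* One-hop indirect linking only; deeper annotation graphs need
  external traversal.
* Organism detection is dictionary-based and misses taxa absent from
  the configured alias list.
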