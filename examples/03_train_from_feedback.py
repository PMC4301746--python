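"""Train a personal ranking profile from graded feedback.

Feedback labels one hit per relevance class; the network is trained on
the labelled feature vectors and afterwards scores a clearly relevant
hit above a clearly irrelevant one.
"""

from traitrank import (
    FeatureConfig,
    Record,
    TrainingConfig,
    build_hit_context,
    build_index,
    expand_query,
    extract_features,
    init_network,
    label_to_target,
    train,
)

records = [
    Record("H1", "curated", {"a": "barley salt stress tolerance gene, characterized"},
           organism="Hordeum vulgare", sequence_length=700),
    Record("H2", "curated", {"a": "salt stress response pathway overview"}),
    Record("H3", "predicted", {"a": "putative fragment mentioning stress once"}),
    Record("H4", "predicted", {"a": "unrelated photosynthesis machinery"}),
]
index = build_index(records)
config = FeatureConfig(
    database_weights={"curated": 0.9, "predicted": 0.3},
    good_keywords=("characterized",),
    bad_keywords=("putative", "fragment"),
    taxonomy=(("barley", "hordeum vulgare"),),
)
query = "barley salt stress"
spec = expand_query(query)

def feats(rec):
    return extract_features(spec, rec, build_hit_context(spec, rec, index), index, config)

feedback = [
    ("H1", "fully agree"),
    ("H2", "could be of relevance"),
    ("H3", "undecided"),
    ("H4", "no relevance"),
]
examples = [(feats(index.records[rid]), label_to_target(label)) for rid, label in feedback]

net = train(init_network(0), examples, TrainingConfig(learning_rate=0.5, epochs=2000))
print(f"training MSE: {net.metadata['initial_mse']:.4f} -> {net.metadata['final_mse']:.4f}")
for rid, label in feedback:
    print(f"{rid} ({label}): score {net.predict(feats(index.records[rid])):.3f}")
# After training, the predicted scores recover the graded feedback
# order: the fully-agreed hit near 1, the irrelevant one near 0.
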