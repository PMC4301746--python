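"""Index a small annotation corpus and run a relevance-ranked search.

Builds four records in memory, indexes them, and searches with the
untrained (seed-0) network: each hit is scored from its 11 relevance
features, shown with its excerpt and hit estimate.
"""

from traitrank import (
    FeatureConfig,
    Record,
    build_index,
    init_network,
    search,
)

records = [
    Record(
        "P001",
        "curated_proteins",
        {
            "description": "sucrose synthase 2 from barley endosperm",
            "function": "catalyzes the reversible cleavage of sucrose",
        },
        organism="Hordeum vulgare",
        sequence_length=805,
    ),
    Record(
        "P002",
        "predicted_proteins",
        {"description": "putative starch synthase fragment"},
        organism="Zea mays",
    ),
    Record(
        "P003",
        "community_notes",
        {"description": "salt stress response regulator in barley"},
        organism="Hordeum vulgare",
    ),
    Record(
        "P004",
        "genome_annotations",
        {"description": "photosynthesis-related thylakoid protein"},
    ),
]

index = build_index(records)
config = FeatureConfig(
    attribute_weights={"description": 0.9, "function": 0.6},
    database_weights={"curated_proteins": 0.9, "predicted_proteins": 0.4},
    taxonomy=(("barley", "hordeum vulgare"),),
)
response = search(index, "barley sucrose synthase", init_network(0), config)

print(f"query: {response.query}")
print(f"estimated results (all terms required): {response.estimated_hits}")
for hit in response.results:
    print(f"{hit.position}. {hit.record_id} [{hit.source_db}] score={hit.score:.4f}")
    print(f"   {hit.snippet.text}")
# The score is the network's relevance prediction in (0,1); the estimate
# counts records containing every query term, while the ranked list also
# includes partial matches.
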