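import pytest

from traitrank.records import Record


@pytest.fixture
def toy_records():
    """Four small records with overlapping vocabulary and cross-refs."""
    return [
        Record(
            "rec1",
            "curated_proteins",
            {
                "description": "sucrose synthase activity in barley",
                "function": "catalyzes sucrose cleavage",
            },
            organism="Hordeum vulgare",
            sequence_length=805,
            cross_refs=("rec9",),
        ),
        Record(
            "rec2",
            "predicted_proteins",
            {"description": "putative starch synthase fragment"},
            organism="Zea mays",
        ),
        Record(
            "rec3",
            "community_notes",
            {"description": "salt stress response gene in barley leaf tissue"},
            organism="Hordeum vulgare",
            sequence_length=1200,
        ),
        Record(
            "rec9",
            "genome_annotations",
            {"description": "photosynthesis related membrane protein"},
        ),
    ]


@pytest.fixture
def toy_index(toy_records):
    from traitrank.index import build_index

    return build_index(toy_records)
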