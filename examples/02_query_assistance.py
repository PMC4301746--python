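"""Query assistance: spelling correction, synonym expansion, related entries.

A misspelled term gets ranked suggestions from the index vocabulary, a
synonym table widens a query into term groups, and document similarity
suggests entries related to a given record.
"""

from traitrank import (
    Record,
    SynonymTable,
    build_index,
    correct_spelling,
    expand_query,
    suggest_related,
)

records = [
    Record("R1", "db", {"a": "barley thermotolerance locus mapping"}),
    Record("R2", "db", {"a": "heat tolerance in barley cultivars"}),
    Record("R3", "db", {"a": "barley yield under drought"}),
    Record("R4", "db", {"a": "barley yield stability analysis"}),
]
index = build_index(records)

print("suggestions for 'barlye':", correct_spelling("barlye", index))
print("suggestions for 'barley':", correct_spelling("barley", index), "(already correct)")

table = SynonymTable({"thermotolerance": {"heat tolerance"}})
spec = expand_query("barley thermotolerance", table)
for group in spec.groups:
    print("group:", [(" ".join(v.tokens), v.origin) for v in group])
# The synonym member lets the search also hit records saying "heat
# tolerance"; its origin flag feeds the synonym feature of the ranker.

print("related to R3:", suggest_related("R3", index, k=2))
# R4 shares the rare terms of R3, so it comes first with the highest
# TF-IDF cosine similarity.
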