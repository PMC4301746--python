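"""Resolve evidence-sorted gene-annotation links for a hit record.

Mapping entries tie genes to records with an evidence class (HC =
high-confidence, LC = low-confidence, blank = N/A).  Links through the
hit record itself are direct; links through one of its cross-references
are indirect (one hop).
"""

from traitrank import MappingEntry, Record, resolve_links

hit = Record(
    "U100", "uniprot_like", {"description": "sucrose synthase, barley"},
    cross_refs=("E200",),
)
neighbour = Record("E200", "genome_like", {"description": "sucrose synthase gene model"})
corpus = {r.record_id: r for r in (hit, neighbour)}

mappings = [
    MappingEntry("HORVU.3050", "U100", "LC"),
    MappingEntry("HORVU.1021", "E200", "HC"),
    MappingEntry("HORVU.0007", "U100", "HC"),
    MappingEntry("HORVU.9999", "U100", "NA"),
]

for link in resolve_links(hit, mappings, corpus):
    print(f"{link.gene_id:12s} via {link.via_record_id}  "
          f"{link.directness:8s} {link.evidence_display}")
# Direct links come first, sorted HC > LC > N/A; the indirect link (via
# the cross-referenced gene model) follows, and genes with no evidence
# sort last, ordered by identifier.
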