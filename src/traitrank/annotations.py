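"""Evidence-sorted gene-annotation link resolution.

Mapping files link gene identifiers to annotation records, each link
carrying an evidence class: high-confidence (HC), low-confidence (LC),
or none (NA, rendered "N/A").  For a hit record, links are resolved
either directly (the mapping names the hit record) or indirectly (the
mapping names one of the hit's cross-references, exactly one hop), and
sorted: direct before indirect; within each, HC, then LC, then NA;
within equal evidence, by ascending gene identifier.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .records import Record

EVIDENCE_CLASSES = ("HC", "LC", "NA")
_EVIDENCE_ORDER = {ev: i for i, ev in enumerate(EVIDENCE_CLASSES)}

DIRECT = "direct"
INDIRECT = "indirect"


@dataclass(frozen=True)
class MappingEntry:
    gene_id: str
    record_id: str
    evidence: str  # HC | LC | NA

    def __post_init__(self) -> None:
        if not self.gene_id or not self.record_id:
            raise ValueError("gene_id and record_id must be non-empty")
        if self.evidence not in EVIDENCE_CLASSES:
            raise ValueError(
                f"evidence must be one of {EVIDENCE_CLASSES}, got {self.evidence!r}"
            )


@dataclass(frozen=True)
class AnnotationLink:
    gene_id: str
    via_record_id: str
    directness: str  # direct | indirect
    evidence: str  # HC | LC | NA

    @property
    def evidence_display(self) -> str:
        """Evidence as rendered to the user; missing evidence is "N/A"."""
        return "N/A" if self.evidence == "NA" else self.evidence


def load_mappings(path: str | Path) -> list[MappingEntry]:
    """Parse a 3-column TSV (gene_id, record_id, evidence).

    Blank evidence means NA.  Lines starting with "#" are comments.
    Raises on a wrong column count or unknown evidence token, naming
    the offending line.
    """
    entries: list[MappingEntry] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].startswith("#"):
                continue
            if len(row) != 3:
                raise ValueError(
                    f"line {lineno}: expected 3 tab-separated columns, got {len(row)}"
                )
            gene_id, record_id, evidence = (c.strip() for c in row)
            evidence = evidence or "NA"
            if evidence not in EVIDENCE_CLASSES:
                raise ValueError(
                    f"line {lineno}: unknown evidence token {evidence!r} "
                    f"(expected one of {EVIDENCE_CLASSES} or blank)"
                )
            entries.append(MappingEntry(gene_id, record_id, evidence))
    return entries


def write_mappings(entries: Iterable[MappingEntry], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for e in entries:
            writer.writerow([e.gene_id, e.record_id, "" if e.evidence == "NA" else e.evidence])


def resolve_links(
    record: Record,
    mappings: Sequence[MappingEntry],
    corpus: Mapping[str, Record],
) -> list[AnnotationLink]:
    """Evidence-sorted annotation links of one hit record.

    Direct links come from mapping entries naming the hit record itself;
    indirect links from entries naming one of its cross-references (one
    hop only, no deeper transitivity).
    """
    if record.record_id not in corpus:
        raise KeyError(f"record {record.record_id!r} not in corpus")
    cross = set(record.cross_refs)
    links = []
    for entry in mappings:
        if entry.record_id == record.record_id:
            directness = DIRECT
        elif entry.record_id in cross:
            directness = INDIRECT
        else:
            continue
        links.append(
            AnnotationLink(entry.gene_id, entry.record_id, directness, entry.evidence)
        )
    links.sort(
        key=lambda l: (
            0 if l.directness == DIRECT else 1,
            _EVIDENCE_ORDER[l.evidence],
            l.gene_id,
            l.via_record_id,
        )
    )
    return links
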