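"""Record model and JSON-lines corpus I/O.

A :class:`Record` is one database entry from an annotation resource: a
unique identifier, the name of the source database, an ordered set of
named free-text attributes (description, function, comment, ...), an
optional organism label, an optional sequence length (residues or
bases), and cross-references to related records.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator


@dataclass(frozen=True)
class Record:
    """One database entry.

    Parameters
    ----------
    record_id:
        Unique, non-empty identifier within a corpus.
    source_db:
        Name of the database the entry comes from.
    attributes:
        Ordered mapping of attribute name to free text.  At least one
        attribute must carry non-empty text.
    organism:
        Optional taxon label (e.g. ``"Hordeum vulgare"``).
    sequence_length:
        Optional non-negative length of the described sequence.
    cross_refs:
        Identifiers of related records (one-hop neighbourhood).
    """

    record_id: str
    source_db: str
    attributes: dict[str, str]
    organism: str | None = None
    sequence_length: int | None = None
    cross_refs: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be non-empty")
        if self.sequence_length is not None and self.sequence_length < 0:
            raise ValueError(
                f"sequence_length must be >= 0, got {self.sequence_length}"
            )
        if not any(text.strip() for text in self.attributes.values()):
            raise ValueError(
                f"record {self.record_id!r} needs at least one non-empty attribute"
            )
        object.__setattr__(self, "cross_refs", tuple(self.cross_refs))

    def to_json_dict(self) -> dict:
        d: dict = {
            "record_id": self.record_id,
            "source_db": self.source_db,
            "attributes": dict(self.attributes),
        }
        if self.organism is not None:
            d["organism"] = self.organism
        if self.sequence_length is not None:
            d["sequence_length"] = self.sequence_length
        if self.cross_refs:
            d["cross_refs"] = list(self.cross_refs)
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "Record":
        return cls(
            record_id=d["record_id"],
            source_db=d["source_db"],
            attributes=dict(d["attributes"]),
            organism=d.get("organism"),
            sequence_length=d.get("sequence_length"),
            cross_refs=tuple(d.get("cross_refs", ())),
        )


def write_records(records: Iterable[Record], path: str | Path) -> None:
    """Write records as UTF-8 JSON-lines, one object per line."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec.to_json_dict(), sort_keys=True))
            fh.write("\n")


def read_records(path: str | Path) -> list[Record]:
    """Read a JSON-lines corpus written by :func:`write_records`."""
    return list(iter_records(path))


def iter_records(path: str | Path) -> Iterator[Record]:
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                yield Record.from_json_dict(json.loads(line))
            except (KeyError, ValueError, TypeError) as exc:
                raise ValueError(f"bad record on line {lineno}: {exc}") from exc
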