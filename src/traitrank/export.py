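"""Ranked-result export as RFC-4180 CSV or XLSX.

One row per result: rank, record_id, source_db, score, the 11 feature
columns in their fixed order, the text excerpt, and the annotation
links joined as ``gene_id|directness|evidence`` with semicolons.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

from .features import FEATURE_NAMES
from .pipeline import SearchResult

EXPORT_COLUMNS: tuple[str, ...] = (
    "rank",
    "record_id",
    "source_db",
    "score",
    *FEATURE_NAMES,
    "excerpt",
    "links",
)


def _result_row(result: SearchResult) -> list:
    links = ";".join(
        f"{l.gene_id}|{l.directness}|{l.evidence_display}" for l in result.links
    )
    return [
        result.position,
        result.record_id,
        result.source_db,
        repr(result.score),
        *[repr(v) for v in result.features],
        result.snippet.text,
        links,
    ]


def export_results(
    results: Sequence[SearchResult], path: str | Path, format: str = "csv"
) -> None:
    """Write results to ``path``; empty input yields a header-only file."""
    if format == "csv":
        with Path(path).open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, lineterminator="\r\n")
            writer.writerow(EXPORT_COLUMNS)
            for res in results:
                writer.writerow(_result_row(res))
    elif format == "xlsx":
        from openpyxl import Workbook

        wb = Workbook()
        ws = wb.active
        ws.title = "results"
        ws.append(list(EXPORT_COLUMNS))
        for res in results:
            ws.append(_result_row(res))
        wb.save(str(path))
    else:
        raise ValueError(f"unknown export format {format!r} (csv or xlsx)")
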