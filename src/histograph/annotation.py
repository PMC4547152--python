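"""Per-image annotations: ordinal scores, class labels and free-text notes.

Scores live on a declared ordinal range (default 0-3, covering the
usual "no abnormality" .. "extreme abnormality" grading); labels are
free strings (e.g. tissue classes such as epithelium / stroma).  Whole
subgroups can be batch-scored, and tables round-trip losslessly through
a fixed-header CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .errors import AnnotationFormatError, DuplicateIdError, InvalidInputError

__all__ = [
    "AnnotationRecord",
    "AnnotationTable",
    "set_annotation",
    "batch_annotate",
    "write_annotations",
    "read_annotations",
]

_COLUMNS = ["image_id", "score", "label", "note", "timestamp"]


@dataclass
class AnnotationRecord:
    score: int | None = None
    label: str | None = None
    note: str | None = None
    timestamp: str | None = None


@dataclass
class AnnotationTable:
    """Mapping image id -> annotation record with a declared score range."""

    records: dict[str, AnnotationRecord] = field(default_factory=dict)
    score_range: tuple[int, int] = (0, 3)

    def _check_score(self, score: int | None) -> None:
        if score is None:
            return
        lo, hi = self.score_range
        if not lo <= score <= hi:
            raise InvalidInputError(
                f"score {score} outside declared range [{lo}, {hi}]"
            )


def _now() -> str:
    return datetime.now(timezone.utc).isoformat()


def set_annotation(
    table: AnnotationTable,
    id: str,
    score: int | None = None,
    label: str | None = None,
    note: str | None = None,
) -> AnnotationTable:
    """Create or update one record; only the supplied fields change and
    the timestamp is refreshed."""
    table._check_score(score)
    rec = table.records.setdefault(id, AnnotationRecord())
    if score is not None:
        rec.score = score
    if label is not None:
        rec.label = label
    if note is not None:
        rec.note = note
    rec.timestamp = _now()
    return table


def batch_annotate(
    table: AnnotationTable, ids: list[str], score: int
) -> AnnotationTable:
    """Give every listed image the same score, leaving labels and notes
    untouched."""
    if not ids:
        raise InvalidInputError("batch_annotate needs at least one id")
    table._check_score(score)
    for img_id in ids:
        rec = table.records.setdefault(img_id, AnnotationRecord())
        rec.score = score
        rec.timestamp = _now()
    return table


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    rows = [
        {
            "image_id": img_id,
            "score": rec.score,
            "label": rec.label,
            "note": rec.note,
            "timestamp": rec.timestamp,
        }
        for img_id, rec in table.records.items()
    ]
    df = pd.DataFrame(rows, columns=_COLUMNS)
    df["score"] = df["score"].astype("Int64")
    df.to_csv(path, index=False)


def read_annotations(
    path: str | Path, score_range: tuple[int, int] = (0, 3)
) -> AnnotationTable:
    """Read a CSV written by :func:`write_annotations` (header
    image_id, score, label, note[, timestamp]); unknown extra columns
    are tolerated.  Malformed rows raise a parse error carrying the
    line number; a repeated image_id raises a duplicate-id error naming
    the id."""
    try:
        df = pd.read_csv(
            Path(path), dtype=str, keep_default_na=False, na_values=[]
        )
    except pd.errors.ParserError as exc:
        raise AnnotationFormatError(f"malformed annotation CSV: {exc}") from exc
    required = {"image_id", "score", "label", "note"}
    if not required <= set(df.columns):
        raise AnnotationFormatError(
            f"annotation CSV must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    dupes = df["image_id"][df["image_id"].duplicated()]
    if len(dupes):
        raise DuplicateIdError(f"duplicate image_id {dupes.iloc[0]!r}")

    table = AnnotationTable(score_range=score_range)
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        raw_score = row.score
        if raw_score == "":
            score = None
        else:
            try:
                score = int(raw_score)
            except ValueError as exc:
                raise AnnotationFormatError(
                    f"line {line_no}: score {raw_score!r} is not an integer"
                ) from exc
        table._check_score(score)
        table.records[row.image_id] = AnnotationRecord(
            score=score,
            label=row.label or None,
            note=row.note or None,
            timestamp=getattr(row, "timestamp", "") or None,
        )
    return table
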