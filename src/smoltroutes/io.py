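"""Tabular input/output for the pipeline.

All pipeline stages exchange plain comma-separated text with a header row,
"." decimal separator and ISO-8601 UTC timestamps, so any stage can be run
standalone on files produced by another.  Readers are strict: a malformed
row is reported with its (1-based, header-exclusive) row number and nothing
is silently dropped -- ``n(input rows) == n(parsed) + n(reported errors)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Detection",
    "TagDeployment",
    "FormatError",
    "DEFAULT_ARRAY_SIZES",
    "read_detections",
    "read_deployments",
    "detections_to_frame",
    "deployments_to_frame",
    "write_table",
    "read_table",
]

SPECIES = {"sockeye", "steelhead"}
TAG_MODELS = {"V7", "V9"}
ORIGINS = {"H", "W", "H/W"}
ARRAYS = {"NSOG", "QCS", "JDF"}

#: receiver-count bound per named array, used for index validation
DEFAULT_ARRAY_SIZES = {"NSOG": 27, "QCS": 44, "JDF": 36}


class FormatError(ValueError):
    """A structural problem in an input table (missing column, bad row)."""


@dataclass(frozen=True)
class Detection:
    """One ping of one tag at one receiver at one instant (UTC)."""

    tag_id: str
    array_name: str
    receiver_index: int
    timestamp: pd.Timestamp


@dataclass(frozen=True)
class TagDeployment:
    """Release metadata for one tagged smolt."""

    tag_id: str
    species: str
    population: str
    origin: str
    fork_length_mm: float
    release_date: pd.Timestamp
    release_year: int
    tag_model: str


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_detections(
    path: str | Path,
    array_sizes: dict[str, int] | None = None,
) -> list[Detection]:
    """Read a detections CSV (columns timestamp, tag_id, array, receiver).

    Returns detections sorted by (tag_id, timestamp, receiver).  Any
    malformed row aborts the read with a :class:`FormatError` naming the
    offending row and value.
    """
    sizes = dict(DEFAULT_ARRAY_SIZES)
    if array_sizes:
        sizes.update(array_sizes)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ["timestamp", "tag_id", "array", "receiver"], path)

    errors: list[str] = []
    out: list[Detection] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        ts = pd.to_datetime(row.timestamp, utc=True, errors="coerce")
        if pd.isna(ts):
            errors.append(f"row {row_no}: unparseable timestamp {row.timestamp!r}")
            continue
        array = row.array.strip()
        if array not in sizes:
            errors.append(f"row {row_no}: unknown array {array!r}")
            continue
        try:
            receiver = int(row.receiver)
        except ValueError:
            errors.append(f"row {row_no}: non-integer receiver {row.receiver!r}")
            continue
        if not 1 <= receiver <= sizes[array]:
            errors.append(
                f"row {row_no}: receiver {receiver} out of range 1..{sizes[array]} on {array}"
            )
            continue
        out.append(Detection(str(row.tag_id), array, receiver, ts))
    if errors:
        raise FormatError(f"{path}: {len(errors)} bad row(s): " + "; ".join(errors))
    out.sort(key=lambda d: (d.tag_id, d.timestamp, d.receiver_index))
    return out


def read_deployments(path: str | Path) -> list[TagDeployment]:
    """Read a tag-deployment CSV; one record per tag, duplicates rejected."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = [
        "tag_id",
        "species",
        "population",
        "origin",
        "fork_length_mm",
        "release_date",
        "release_year",
        "tag_model",
    ]
    _require_columns(df, cols, path)
    errors: list[str] = []
    out: list[TagDeployment] = []
    seen: set[str] = set()
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        tag = str(row.tag_id)
        if tag in seen:
            errors.append(f"row {row_no}: duplicate tag_id {tag!r}")
            continue
        seen.add(tag)
        if row.species not in SPECIES:
            errors.append(f"row {row_no}: unknown species {row.species!r}")
            continue
        if row.tag_model not in TAG_MODELS:
            errors.append(f"row {row_no}: unknown tag_model {row.tag_model!r}")
            continue
        if row.origin not in ORIGINS:
            errors.append(f"row {row_no}: unknown origin {row.origin!r}")
            continue
        try:
            fl = float(row.fork_length_mm)
        except ValueError:
            fl = np.nan
        if not fl > 0:
            errors.append(f"row {row_no}: fork_length_mm {row.fork_length_mm!r} not positive")
            continue
        rel = pd.to_datetime(row.release_date, utc=True, errors="coerce")
        if pd.isna(rel):
            errors.append(f"row {row_no}: unparseable release_date {row.release_date!r}")
            continue
        try:
            year = int(row.release_year)
        except ValueError:
            errors.append(f"row {row_no}: bad release_year {row.release_year!r}")
            continue
        out.append(
            TagDeployment(tag, row.species, row.population, row.origin, fl, rel, year, row.tag_model)
        )
    if errors:
        raise FormatError(f"{path}: {len(errors)} bad row(s): " + "; ".join(errors))
    return out


def detections_to_frame(detections: list[Detection]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "timestamp": [d.timestamp for d in detections],
            "tag_id": [d.tag_id for d in detections],
            "array": [d.array_name for d in detections],
            "receiver": [d.receiver_index for d in detections],
        }
    )


def deployments_to_frame(deployments: list[TagDeployment]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(d) for d in deployments])


def write_table(records, path: str | Path) -> None:
    """Write records (DataFrame or list of dataclasses) as CSV.

    Floats keep full precision (round-trip within 1e-9); timestamps are
    ISO-8601 UTC.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    elif len(records) == 0:
        raise ValueError("cannot infer a header from an empty record list; pass a DataFrame")
    else:
        df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    for col in df.columns:
        if pd.api.types.is_datetime64_any_dtype(df[col]):
            df[col] = df[col].dt.strftime("%Y-%m-%dT%H:%M:%S.%f%z")
    df.to_csv(path, index=False, float_format="%.12g")


def read_table(path: str | Path, parse_dates: list[str] | None = None) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    df = pd.read_csv(path)
    for col in parse_dates or []:
        if col in df.columns:
            df[col] = pd.to_datetime(df[col], utc=True)
    return df
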