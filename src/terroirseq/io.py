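"""TSV/JSON/YAML readers and writers for the shared data model.

Count tables round-trip exactly: ``read_count_table(write_count_table(t))``
reproduces ``t``.  Malformed files (duplicate ids, ragged rows, negative or
non-integer counts) are rejected with messages naming the offending row or
column.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .datamodel import CountTable, SampleMetadata, ValidationError

ANNOTATION_COLUMNS = ("taxonomy", "organism")


def read_count_table(path: str | Path, marker: str) -> CountTable:
    """Read a features-in-rows TSV count table.

    The first column is the feature id; ``taxonomy`` / ``organism``
    columns, if present, are treated as annotation; all remaining columns
    are samples.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ValidationError(f"malformed count table {path}: {exc}") from exc
    if raw.isna().any().any():
        bad_rows = raw.index[raw.isna().any(axis=1)]
        raise ValidationError(
            f"{path}: ragged or missing values in row(s) {list(bad_rows[:5])}"
        )
    annotations: dict[str, pd.Series] = {}
    for col in ANNOTATION_COLUMNS:
        if col in raw.columns:
            annotations[col] = raw.pop(col)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = numeric.columns[numeric.isna().any(axis=0)]
        raise ValidationError(f"{path}: non-numeric counts in column(s) {list(bad[:5])}")
    return CountTable(
        counts=numeric,
        marker=marker,
        taxonomy=annotations.get("taxonomy"),
        organism=annotations.get("organism"),
    )


def write_count_table(table: CountTable, path: str | Path) -> None:
    path = Path(path)
    out = table.counts.copy()
    if table.organism is not None:
        out.insert(0, "organism", table.organism)
    if table.taxonomy is not None:
        out.insert(0, "taxonomy", table.taxonomy)
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> SampleMetadata:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    for col in ("site", "region", "vintage", "tank"):
        if col in frame.columns:
            frame[col] = frame[col].astype(str)
    return SampleMetadata(frame)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    out = meta.frame.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def write_distance_matrix(dm, path: str | Path) -> None:
    frame = dm.to_frame()
    frame.index.name = "sample_id"
    frame.to_csv(path, sep="\t")


def read_json(path: str | Path) -> Any:
    with open(path) as fh:
        return json.load(fh)


def write_json(obj: Any, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_yaml(path: str | Path) -> Any:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(obj: Any, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
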