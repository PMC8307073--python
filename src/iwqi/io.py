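"""CSV/YAML readers and provenance-stamped writers."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .core import (
    DEFAULT_CATALOG,
    ParameterCatalog,
    SampleTable,
    SchemaError,
    StandardsTable,
    ValidationError,
    validate_sample_table,
)
from .weighting import LiteratureWeightDB

__all__ = [
    "read_samples",
    "write_samples",
    "read_weight_db",
    "write_weight_db",
    "read_standards",
    "write_report",
]

_COORD_COLUMNS = ("x", "y")


def read_samples(
    path, catalog: ParameterCatalog = DEFAULT_CATALOG, missing_policy: str = "reject"
) -> SampleTable:
    """Read and validate a sample CSV (sample_id, season, 14 parameters)."""
    frame = pd.read_csv(path, comment="#")
    for required in ("sample_id", "season"):
        if required not in frame.columns:
            raise SchemaError(f"sample CSV is missing the {required!r} column")
    if frame.empty:
        raise ValidationError(f"no samples in {path}")
    dup = frame["sample_id"][frame["sample_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"duplicate sample_id(s): {sorted(dup.unique())}")
    frame = frame.set_index("sample_id")
    seasons = frame.pop("season").astype(str)
    coords = None
    present_coords = [c for c in _COORD_COLUMNS if c in frame.columns]
    if present_coords:
        coords = frame[present_coords].astype(float)
        frame = frame.drop(columns=present_coords)
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric cell in {path}: {exc}") from exc
    table = SampleTable(frame, seasons, catalog=catalog, coordinates=coords)
    return validate_sample_table(table, catalog, missing_policy=missing_policy)


def write_samples(table: SampleTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_weight_db(path) -> LiteratureWeightDB:
    """Read a literature weight CSV (study label + parameter columns,
    blank = missing)."""
    frame = pd.read_csv(path, index_col=0)
    if frame.empty:
        raise ValidationError(f"weight database {path} is empty")
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric weight in {path}: {exc}") from exc
    return LiteratureWeightDB(frame)


def write_weight_db(db: LiteratureWeightDB, path) -> None:
    db.table.rename_axis("study").to_csv(path)


def read_standards(path) -> StandardsTable:
    return StandardsTable.from_yaml(path)


def config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_report(frame: pd.DataFrame, path, provenance: dict, index: bool = True) -> None:
    """Write a CSV with a commented provenance header (seed, config hash...)."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in provenance.items():
            fh.write(f"# {key}: {value}\n")
        frame.to_csv(fh, index=index)


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
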