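"""Reading and writing cohort directories.

A cohort is a directory of five long-format tables — ``encounters``,
``observations``, ``med_admin``, ``orders``, ``predictions`` — plus an
optional ``truth`` table for synthetic cohorts.  Two dialects are
supported: plain CSV with ISO-8601 timestamps, and Parquet.  Reading
validates the schema and raises :class:`~sepsisval.errors.SchemaError`
naming the file and the missing column.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import SchemaError
from .synthetic import SyntheticCohort

_TS = "datetime64[ns]"

#: table name -> ordered {column: dtype}; datetime columns may contain NaT.
SCHEMAS: dict[str, dict[str, str]] = {
    "encounters": {
        "encounter_id": "object",
        "age": "int64",
        "sex": "object",
        "race": "object",
        "ethnicity": "object",
        "presentation_ts": _TS,
        "discharge_ts": _TS,
        "death_ts": _TS,
    },
    "observations": {
        "encounter_id": "object",
        "ts": _TS,
        "kind": "object",
        "value": "float64",
        "unit": "object",
    },
    "med_admin": {
        "encounter_id": "object",
        "ts": _TS,
        "drug_class": "object",
        "route": "object",
        "dose": "float64",
    },
    "orders": {
        "encounter_id": "object",
        "ts": _TS,
        "order_kind": "object",
    },
    "predictions": {
        "encounter_id": "object",
        "model_id": "object",
        "ts": _TS,
        "score": "int64",
    },
    "truth": {
        "encounter_id": "object",
        "is_septic": "bool",
        "onset_ts": _TS,
        "si_ts": _TS,
        "sofa_cross_ts": _TS,
        "expected_recognition_ts": _TS,
        "borderline": "bool",
    },
}

_ISO = "%Y-%m-%dT%H:%M:%S"


def write_cohort(cohort: SyntheticCohort, directory: str | Path, fmt: str = "csv") -> list[Path]:
    """Write the cohort tables to ``directory``; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, schema in SCHEMAS.items():
        df = getattr(cohort, name)
        if df is None:
            continue
        df = df[list(schema)]
        if fmt == "csv":
            path = directory / f"{name}.csv"
            df.to_csv(path, index=False, date_format=_ISO)
        elif fmt == "parquet":
            path = directory / f"{name}.parquet"
            df.to_parquet(path, index=False)
        else:
            raise SchemaError(f"unknown cohort format {fmt!r}")
        written.append(path)
    return written


def _coerce(df: pd.DataFrame, schema: dict[str, str], path: Path) -> pd.DataFrame:
    for col, dtype in schema.items():
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing required column '{col}'")
    df = df[list(schema)].copy()
    for col, dtype in schema.items():
        if dtype == _TS:
            df[col] = pd.to_datetime(df[col], format="ISO8601" if df[col].dtype == object else None)
        elif df[col].dtype != dtype:
            df[col] = df[col].astype(dtype)
    return df


def read_cohort(directory: str | Path) -> SyntheticCohort:
    """Read a cohort directory written by :func:`write_cohort` (either dialect)."""
    directory = Path(directory)
    tables: dict[str, pd.DataFrame | None] = {}
    for name, schema in SCHEMAS.items():
        csv_path = directory / f"{name}.csv"
        pq_path = directory / f"{name}.parquet"
        if csv_path.exists():
            df = pd.read_csv(csv_path)
            tables[name] = _coerce(df, schema, csv_path)
        elif pq_path.exists():
            df = pd.read_parquet(pq_path)
            tables[name] = _coerce(df, schema, pq_path)
        elif name == "truth":
            tables[name] = None
        else:
            raise SchemaError(f"cohort table '{name}' not found in {directory}")
    return SyntheticCohort(**tables)  # type: ignore[arg-type]
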