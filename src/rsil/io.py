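"""CSV/JSON/YAML input and output.

One exchange format: RFC-4180 CSV, UTF-8, '.' decimal. The measurement
schema is long-format with columns day, microcosm_id, treatment and at least
one of delta13c_permil / sulfate_mM / cells_per_ml. Reports are JSON with
sorted keys for diffability.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Literal, Optional, Union

import pandas as pd
import yaml
from pydantic import BaseModel, ValidationError, model_validator

from rsil.errors import ParseError

KEY_COLUMNS = ["day", "microcosm_id", "treatment"]
MEASUREMENT_COLUMNS = ["delta13c_permil", "sulfate_mM", "cells_per_ml"]
ALL_COLUMNS = KEY_COLUMNS + MEASUREMENT_COLUMNS


class MeasurementRecord(BaseModel):
    """One row of the long-format measurement table."""

    day: float
    microcosm_id: str
    treatment: Literal["live", "autoclaved"]
    delta13c_permil: Optional[float] = None
    sulfate_mM: Optional[float] = None
    cells_per_ml: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "MeasurementRecord":
        if self.day < 0:
            raise ValueError(f"day must be >= 0, got {self.day}")
        values = [getattr(self, c) for c in MEASUREMENT_COLUMNS]
        if all(v is None or math.isnan(v) for v in values):
            raise ValueError("record has no measurement (all variables null)")
        return self


def read_measurements(
    path: Union[str, Path], strict: bool = False
) -> list[MeasurementRecord]:
    """Read and validate a measurement CSV.

    Unknown columns are rejected in strict mode and warned about otherwise.
    Errors name the offending 1-based file row (header = row 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: cannot parse CSV: {exc}") from exc
    if df.empty and df.columns.size == 0:
        raise ParseError(f"{path}: empty file")

    missing = [c for c in KEY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    present_measurements = [c for c in MEASUREMENT_COLUMNS if c in df.columns]
    if not present_measurements:
        raise ParseError(
            f"{path}: need at least one measurement column of {MEASUREMENT_COLUMNS}"
        )
    unknown = [c for c in df.columns if c not in ALL_COLUMNS]
    if unknown:
        if strict:
            raise ParseError(f"{path}: unknown columns {unknown} (strict mode)")
        import warnings as _warnings

        _warnings.warn(f"{path}: ignoring unknown columns {unknown}", stacklevel=2)

    records: list[MeasurementRecord] = []
    seen: dict[tuple, int] = {}
    for idx, row in df.iterrows():
        file_row = int(idx) + 2  # header is row 1
        payload: dict = {}
        for col in KEY_COLUMNS:
            payload[col] = row[col]
        for col in present_measurements:
            raw = str(row[col]).strip()
            payload[col] = None if raw == "" else raw
        try:
            rec = MeasurementRecord(**payload)
        except (ValidationError, ValueError) as exc:
            raise ParseError(f"{path}: row {file_row}: {exc}") from exc
        for col in present_measurements:
            if getattr(rec, col) is None:
                continue
            key = (rec.day, rec.microcosm_id, col)
            if key in seen:
                raise ParseError(
                    f"{path}: row {file_row}: duplicate value for {col} at "
                    f"(day={rec.day:g}, microcosm={rec.microcosm_id!r}); "
                    f"first seen at row {seen[key]}"
                )
            seen[key] = file_row
        records.append(rec)
    if not records:
        raise ParseError(f"{path}: no data rows")
    return records


def records_to_frame(records: list[MeasurementRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.model_dump() for r in records], columns=ALL_COLUMNS)


def write_measurements(table: pd.DataFrame, path: Union[str, Path]) -> None:
    table.to_csv(path, index=False)


def write_report_json(report: dict, path: Union[str, Path]) -> None:
    """Stable, diffable JSON: sorted keys, trailing newline."""
    Path(path).write_text(
        json.dumps(report, sort_keys=True, indent=2, allow_nan=True) + "\n",
        encoding="utf-8",
    )


RATES_CSV_COLUMNS = [
    "microcosm_id",
    "treatment",
    "interval_start_day",
    "interval_end_day",
    "method",
    "basis",
    "value",
    "units",
]


def write_rates_csv(report: dict, path: Union[str, Path]) -> None:
    rows = [{k: r.get(k) for k in RATES_CSV_COLUMNS} for r in report["rates"]]
    pd.DataFrame(rows, columns=RATES_CSV_COLUMNS).to_csv(path, index=False)


def write_flags_csv(report: dict, path: Union[str, Path]) -> None:
    cols = ["flag", "microcosm_id", "day", "detail"]
    pd.DataFrame(report["flags"], columns=cols).to_csv(path, index=False)


def load_config_file(path: Union[str, Path]) -> dict:
    """Load a flat key-value config (YAML/JSON); returns a plain dict."""
    text = Path(path).read_text(encoding="utf-8")
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ParseError(f"{path}: cannot parse config: {exc}") from exc
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ParseError(f"{path}: config must be a mapping of key: value pairs")
    return data


def split_config(
    overrides: dict, *model_classes: type[BaseModel]
) -> list[dict]:
    """Partition flat overrides among pydantic models; unknown keys error."""
    buckets = [dict() for _ in model_classes]
    for key, value in overrides.items():
        hit = False
        for bucket, cls in zip(buckets, model_classes):
            if key in cls.model_fields:
                bucket[key] = value
                hit = True
        if not hit:
            known = sorted({k for cls in model_classes for k in cls.model_fields})
            raise ParseError(f"unknown config key {key!r}; known keys: {known}")
    return buckets
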