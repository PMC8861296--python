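"""Typed on-disk schemas for the raw clinical tables and pipeline outputs.

Every table is a plain CSV with ISO-8601 timestamps; ``patient_id`` is the
join key across tables.  Each schema has a frozen dataclass record type whose
construction enforces the row-level invariants (positive doses, non-negative
concentrations, known analytes, valid ATC level-1 letters).  :func:`read_table`
validates row by row and collects failures with their line numbers instead of
silently dropping them; :func:`write_table` is its exact inverse so that a
write/read round trip reproduces the record set field for field.

Missing lab values are encoded as absent rows, never as sentinel values:
missingness is reconstructed downstream at feature-building time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

#: The 14 anatomical main groups of the ATC classification, level 1.
ATC_LEVEL1 = frozenset("ABCDGHJLMNPRSV")

#: Known chemistry analytes (units: µmol/L, g/L, mL/min/1.73m²).
ANALYTES = ("serum_creatinine", "albumin", "egfr")

TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M"  # minute resolution


class SchemaError(ValueError):
    """The file header does not match the requested schema."""


@dataclass(frozen=True)
class RowError:
    """A single row that failed validation (1-based data line number)."""

    line: int
    message: str


class TableValidationError(ValueError):
    """Raised when a table contains rows violating the schema invariants."""

    def __init__(self, path: str, errors: Sequence[RowError]):
        self.errors = list(errors)
        lines = "; ".join(f"line {e.line}: {e.message}" for e in self.errors[:5])
        more = "" if len(self.errors) <= 5 else f" (+{len(self.errors) - 5} more)"
        super().__init__(f"{path}: {len(self.errors)} invalid row(s): {lines}{more}")


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


def _parse_time(value) -> pd.Timestamp:
    ts = pd.Timestamp(value)
    _check(not pd.isna(ts), "unparseable timestamp")
    return ts.floor("min")


@dataclass(frozen=True)
class InjectionEvent:
    """One vancomycin administration (dose in mg per administration)."""

    patient_id: str
    time: pd.Timestamp
    dose_mg: float

    def __post_init__(self):
        _check(bool(self.patient_id), "patient_id must be non-empty")
        object.__setattr__(self, "time", _parse_time(self.time))
        object.__setattr__(self, "dose_mg", float(self.dose_mg))
        _check(self.dose_mg > 0, f"dose_mg must be > 0, got {self.dose_mg}")


@dataclass(frozen=True)
class TroughMeasurement:
    """Serum vancomycin concentration drawn before a dose (mcg/mL)."""

    patient_id: str
    time: pd.Timestamp
    concentration: float

    def __post_init__(self):
        _check(bool(self.patient_id), "patient_id must be non-empty")
        object.__setattr__(self, "time", _parse_time(self.time))
        object.__setattr__(self, "concentration", float(self.concentration))
        _check(self.concentration >= 0, "concentration must be >= 0")


@dataclass(frozen=True)
class LabResult:
    """Chemistry result: serum creatinine (µmol/L), albumin (g/L) or eGFR."""

    patient_id: str
    time: pd.Timestamp
    analyte: str
    value: float

    def __post_init__(self):
        _check(bool(self.patient_id), "patient_id must be non-empty")
        object.__setattr__(self, "time", _parse_time(self.time))
        _check(self.analyte in ANALYTES, f"unknown analyte {self.analyte!r}")
        object.__setattr__(self, "value", float(self.value))
        _check(self.value >= 0, "lab value must be >= 0")


@dataclass(frozen=True)
class DispensingEvent:
    """One medication dispensing, coded with an ATC code."""

    patient_id: str
    time: pd.Timestamp
    atc_code: str

    def __post_init__(self):
        _check(bool(self.patient_id), "patient_id must be non-empty")
        object.__setattr__(self, "time", _parse_time(self.time))
        _check(
            bool(self.atc_code) and self.atc_code[0] in ATC_LEVEL1,
            f"ATC code must start with a level-1 letter, got {self.atc_code!r}",
        )


@dataclass(frozen=True)
class PatientDemographics:
    patient_id: str
    age_years: float
    is_female: bool
    weight_kg: float

    def __post_init__(self):
        _check(bool(self.patient_id), "patient_id must be non-empty")
        object.__setattr__(self, "age_years", float(self.age_years))
        _check(self.age_years >= 0, "age_years must be >= 0")
        object.__setattr__(self, "is_female", _parse_bool(self.is_female))
        object.__setattr__(self, "weight_kg", float(self.weight_kg))
        _check(self.weight_kg > 0, "weight_kg must be > 0")


@dataclass(frozen=True)
class HemodialysisFlag:
    """One hemodialysis session."""

    patient_id: str
    time: pd.Timestamp

    def __post_init__(self):
        _check(bool(self.patient_id), "patient_id must be non-empty")
        object.__setattr__(self, "time", _parse_time(self.time))


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        if math.isnan(value) if isinstance(value, float) else False:
            raise ValueError("boolean field is NaN")
        _check(value in (0, 1), f"boolean field must be 0/1, got {value}")
        return bool(value)
    s = str(value).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValueError(f"cannot parse boolean {value!r}")


# ---------------------------------------------------------------------------
# schema registry

SCHEMAS = {
    "injections": InjectionEvent,
    "troughs": TroughMeasurement,
    "labs": LabResult,
    "dispensing": DispensingEvent,
    "demographics": PatientDemographics,
    "hemodialysis": HemodialysisFlag,
}

#: Conventional file name per table kind.
TABLE_FILES = {kind: f"{kind}.csv" for kind in SCHEMAS}


def _columns(record_type) -> list[str]:
    return [f.name for f in dc_fields(record_type)]


def read_table(path, schema: str):
    """Read and validate one CSV table.

    Parameters
    ----------
    path
        CSV file with a header matching the schema's column names.
    schema
        Table kind, one of ``injections, troughs, labs, dispensing,
        demographics, hemodialysis``.

    Returns
    -------
    list of typed records (dataclass instances).

    Raises
    ------
    SchemaError
        if a required column is missing.
    TableValidationError
        if any row violates the type invariants; the exception carries all
        offending rows with their data line numbers.
    """
    record_type = SCHEMAS[schema]
    cols = _columns(record_type)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    records = []
    errors: list[RowError] = []
    for i, row in enumerate(df.itertuples(index=False)):
        kwargs = {c: getattr(row, c) for c in cols}
        try:
            records.append(record_type(**kwargs))
        except (ValueError, TypeError) as exc:
            errors.append(RowError(line=i + 1, message=str(exc)))
    if errors:
        raise TableValidationError(str(path), errors)
    return records


def write_table(records: Iterable, path, schema: str | None = None) -> None:
    """Write homogeneous records to CSV; inverse of :func:`read_table`.

    ``schema`` is only needed for an empty record list (to pick the header).
    Timestamps are serialized ISO-8601 at minute resolution, so lexicographic
    order of the serialized strings equals chronological order.
    """
    records = list(records)
    if records:
        record_type = type(records[0])
        _check(
            all(type(r) is record_type for r in records),
            "records must be homogeneous",
        )
    elif schema is not None:
        record_type = SCHEMAS[schema]
    else:
        raise ValueError("schema required to write an empty table")
    cols = _columns(record_type)
    rows = []
    for r in records:
        row = {}
        for c in cols:
            v = getattr(r, c)
            if isinstance(v, pd.Timestamp):
                v = v.strftime(TIMESTAMP_FORMAT)
            elif isinstance(v, bool):
                v = int(v)
            row[c] = v
        rows.append(row)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def to_frame(records: Iterable, schema: str | None = None) -> pd.DataFrame:
    """Records as a DataFrame (the working container for the pipeline)."""
    records = list(records)
    if not records:
        if schema is None:
            raise ValueError("schema required for an empty record list")
        return pd.DataFrame(columns=_columns(SCHEMAS[schema]))
    cols = _columns(type(records[0]))
    return pd.DataFrame({c: [getattr(r, c) for r in records] for c in cols})


def from_frame(df: pd.DataFrame, schema: str):
    """DataFrame rows as validated typed records."""
    record_type = SCHEMAS[schema]
    cols = _columns(record_type)
    return [record_type(**{c: row[c] for c in cols}) for _, row in df.iterrows()]
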