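"""Typed data model for audited OHCA emergency calls.

One :class:`CallRecord` per emergency call, with event times in seconds from
the moment the call was answered, dispatcher recognition and barrier flags,
patient/caller covariates and 30-day survival.  Every nullable field has an
explicit MISSING state (``None``), distinguishable from ``False``/``0``.

The on-disk format is a UTF-8 comma-separated table with a fixed header
(see :data:`COLUMNS`).  MISSING is written as an empty cell; ``NA`` is also
accepted on read for interoperability.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "RecognizabilityBarrier",
    "DacprBarrier",
    "Sex",
    "Location",
    "Cause",
    "CallRecord",
    "COLUMNS",
    "read_call_table",
    "write_call_table",
    "validate_record",
    "validate_cohort",
    "CallTableError",
]


class CallTableError(ValueError):
    """Raised for malformed call tables (bad cell, duplicate id, bad schema)."""


class RecognizabilityBarrier(enum.Enum):
    """Why a call was not recognizable as OHCA by the dispatcher."""

    NONE = "NONE"
    THIRD_PARTY = "THIRD_PARTY"
    HYSTERICAL = "HYSTERICAL"
    HANG_UP = "HANG_UP"
    LANGUAGE = "LANGUAGE"
    OTHER = "OTHER"


class DacprBarrier(enum.Enum):
    """Caller-side barrier to dispatcher-assisted CPR in a recognized OHCA."""

    NONE = "NONE"
    CANNOT_MOVE = "CANNOT_MOVE"
    REFUSES = "REFUSES"
    HANG_UP = "HANG_UP"
    NOT_WITH_PATIENT = "NOT_WITH_PATIENT"
    OTHER = "OTHER"


class Sex(enum.Enum):
    FEMALE = "FEMALE"
    MALE = "MALE"


class Location(enum.Enum):
    RESIDENTIAL = "RESIDENTIAL"
    PUBLIC = "PUBLIC"
    OTHER = "OTHER"


class Cause(enum.Enum):
    CARDIAC = "CARDIAC"
    OVERDOSE = "OVERDOSE"
    TRAUMA = "TRAUMA"
    RESPIRATORY = "RESPIRATORY"
    ASPHYXIA = "ASPHYXIA"
    SUICIDE = "SUICIDE"
    SUBMERSION = "SUBMERSION"
    SIDS = "SIDS"
    OTHER = "OTHER"


@dataclass
class CallRecord:
    """One audited OHCA emergency call.

    Time fields are seconds from call answer; ``None`` means MISSING.
    """

    call_id: str
    recognized: bool = False
    alive_during_call: bool = False
    audio_available: bool = True
    cpr_in_progress: bool = False
    dacpr_compressions_given: bool = False
    recognizability_barrier: RecognizabilityBarrier = RecognizabilityBarrier.NONE
    dacpr_barrier: DacprBarrier = DacprBarrier.NONE
    t_recognition_s: Optional[float] = None
    t_dispatch_s: Optional[float] = None
    t_cpr_instruction_s: Optional[float] = None
    t_first_compression_s: Optional[float] = None
    t_first_dacpr_compression_s: Optional[float] = None
    any_compression_during_call: Optional[bool] = None
    survived_30d: Optional[bool] = None
    patient_age: Optional[float] = None
    patient_sex: Optional[Sex] = None
    caller_sex: Optional[Sex] = None
    caller_alone: Optional[bool] = None
    caller_hcp: Optional[bool] = None
    caller_knows_victim: Optional[bool] = None
    location: Optional[Location] = None
    witnessed: Optional[bool] = None
    cause: Optional[Cause] = None
    shockable_rhythm: Optional[bool] = None
    aed_addressed: Optional[bool] = None
    call_continued_until_ems: Optional[bool] = None


#: canonical column order of the call table
COLUMNS: tuple[str, ...] = (
    "call_id",
    "t_recognition_s",
    "t_dispatch_s",
    "t_cpr_instruction_s",
    "t_first_compression_s",
    "t_first_dacpr_compression_s",
    "recognized",
    "alive_during_call",
    "audio_available",
    "cpr_in_progress",
    "recognizability_barrier",
    "dacpr_barrier",
    "any_compression_during_call",
    "dacpr_compressions_given",
    "survived_30d",
    "patient_age",
    "patient_sex",
    "caller_sex",
    "caller_alone",
    "caller_hcp",
    "caller_knows_victim",
    "location",
    "witnessed",
    "cause",
    "shockable_rhythm",
    "aed_addressed",
    "call_continued_until_ems",
)

_TIME_COLUMNS = (
    "t_recognition_s",
    "t_dispatch_s",
    "t_cpr_instruction_s",
    "t_first_compression_s",
    "t_first_dacpr_compression_s",
)
_REQUIRED_BOOL_COLUMNS = (
    "recognized",
    "alive_during_call",
    "audio_available",
    "cpr_in_progress",
    "dacpr_compressions_given",
)
_NULLABLE_BOOL_COLUMNS = (
    "any_compression_during_call",
    "survived_30d",
    "caller_alone",
    "caller_hcp",
    "caller_knows_victim",
    "witnessed",
    "shockable_rhythm",
    "aed_addressed",
    "call_continued_until_ems",
)
_ENUM_COLUMNS = {
    "recognizability_barrier": RecognizabilityBarrier,
    "dacpr_barrier": DacprBarrier,
    "patient_sex": Sex,
    "caller_sex": Sex,
    "location": Location,
    "cause": Cause,
}
_MISSING_TOKENS = {"", "NA"}

_TRUE_TOKENS = {"1", "true"}
_FALSE_TOKENS = {"0", "false"}


def _parse_bool(token: str, *, row: int, column: str, nullable: bool) -> Optional[bool]:
    if token in _MISSING_TOKENS:
        if nullable:
            return None
        raise CallTableError(f"row {row}, column {column!r}: value required, got {token!r}")
    low = token.strip().lower()
    if low in _TRUE_TOKENS:
        return True
    if low in _FALSE_TOKENS:
        return False
    raise CallTableError(f"row {row}, column {column!r}: not a boolean: {token!r}")


def _parse_time(token: str, *, row: int, column: str) -> Optional[float]:
    if token in _MISSING_TOKENS:
        return None
    try:
        value = float(token)
    except ValueError as exc:
        raise CallTableError(f"row {row}, column {column!r}: not a number: {token!r}") from exc
    if not math.isfinite(value):
        raise CallTableError(f"row {row}, column {column!r}: non-finite time {token!r}")
    if value < 0:
        raise CallTableError(f"row {row}, column {column!r}: negative time {value}")
    return value


def _parse_enum(token: str, enum_cls, *, row: int, column: str, nullable: bool):
    if token in _MISSING_TOKENS:
        if nullable:
            return None
        raise CallTableError(f"row {row}, column {column!r}: value required, got {token!r}")
    try:
        return enum_cls[token.strip().upper()]
    except KeyError as exc:
        allowed = ", ".join(m.name for m in enum_cls)
        raise CallTableError(
            f"row {row}, column {column!r}: unknown label {token!r} (allowed: {allowed})"
        ) from exc


def read_call_table(path, **csv_options) -> list[CallRecord]:
    """Read a call table into a list of :class:`CallRecord`.

    Empty cells and ``NA`` map to MISSING; booleans accept ``0/1/true/false``
    case-insensitively.  Unknown columns are ignored with a warning; unknown
    enum labels, duplicate call ids and negative times raise
    :class:`CallTableError` naming the row and column.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False, **csv_options)
    missing_cols = [c for c in COLUMNS if c not in frame.columns]
    if missing_cols:
        raise CallTableError(f"{path}: missing required columns: {missing_cols}")
    unknown = [c for c in frame.columns if c not in COLUMNS]
    if unknown:
        warnings.warn(f"{path}: ignoring unknown columns {unknown}", stacklevel=2)

    records: list[CallRecord] = []
    seen_ids: set[str] = set()
    for i, row in enumerate(frame.itertuples(index=False), start=2):  # 1-based + header
        cells = dict(zip(frame.columns, row))
        call_id = cells["call_id"].strip()
        if call_id in _MISSING_TOKENS:
            raise CallTableError(f"row {i}, column 'call_id': empty identifier")
        if call_id in seen_ids:
            raise CallTableError(f"row {i}, column 'call_id': duplicate call_id {call_id!r}")
        seen_ids.add(call_id)

        kwargs: dict = {"call_id": call_id}
        for col in _TIME_COLUMNS:
            kwargs[col] = _parse_time(cells[col], row=i, column=col)
        for col in _REQUIRED_BOOL_COLUMNS:
            kwargs[col] = _parse_bool(cells[col], row=i, column=col, nullable=False)
        for col in _NULLABLE_BOOL_COLUMNS:
            kwargs[col] = _parse_bool(cells[col], row=i, column=col, nullable=True)
        for col, enum_cls in _ENUM_COLUMNS.items():
            nullable = col not in ("recognizability_barrier", "dacpr_barrier")
            kwargs[col] = _parse_enum(cells[col], enum_cls, row=i, column=col, nullable=nullable)
        age = cells["patient_age"]
        if age in _MISSING_TOKENS:
            kwargs["patient_age"] = None
        else:
            try:
                kwargs["patient_age"] = float(age)
            except ValueError as exc:
                raise CallTableError(
                    f"row {i}, column 'patient_age': not a number: {age!r}"
                ) from exc
        records.append(CallRecord(**kwargs))
    return records


def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, enum.Enum):
        return value.name
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(int(value)) if value == int(value) else repr(value)
    return str(value)


def write_call_table(records: Iterable[CallRecord], path) -> None:
    """Write records as CSV in the canonical column order; MISSING → empty cell."""
    rows = [{col: _format_cell(getattr(r, col)) for col in COLUMNS} for r in records]
    frame = pd.DataFrame(rows, columns=list(COLUMNS))
    frame.to_csv(Path(path), index=False)


def validate_record(record: CallRecord) -> list[str]:
    """Return a violation description per broken invariant (empty list = valid)."""
    violations: list[str] = []
    for col in _TIME_COLUMNS:
        value = getattr(record, col)
        if value is None:
            continue
        if not math.isfinite(value):
            violations.append(f"{col}: non-finite value {value!r}")
        elif value < 0:
            violations.append(f"{col}: negative time {value!r}")
    if record.patient_age is not None and (
        not math.isfinite(record.patient_age) or record.patient_age < 0
    ):
        violations.append(f"patient_age: invalid value {record.patient_age!r}")
    if record.dacpr_compressions_given and not record.recognized:
        violations.append(
            "dacpr_compressions_given: directed compressions require recognized=true"
        )
    if record.t_first_dacpr_compression_s is not None and not record.dacpr_compressions_given:
        violations.append(
            "t_first_dacpr_compression_s: time present but dacpr_compressions_given=false"
        )
    if record.t_recognition_s is not None and not record.recognized:
        violations.append("t_recognition_s: time present but recognized=false")
    return violations


def validate_cohort(records: Sequence[CallRecord]) -> None:
    """Raise :class:`CallTableError` listing every invalid record in a cohort."""
    problems = []
    seen: set[str] = set()
    for r in records:
        if r.call_id in seen:
            problems.append(f"{r.call_id}: duplicate call_id")
        seen.add(r.call_id)
        for v in validate_record(r):
            problems.append(f"{r.call_id}: {v}")
    if problems:
        raise CallTableError("invalid cohort:\n" + "\n".join(problems))
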