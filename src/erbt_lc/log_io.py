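"""Procedure-log data contracts, CSV round-tripping and validation.

A procedure log records one row per resection event: who operated
(``operator_id``, with a ``seniority`` label of ``junior`` or ``senior``),
the 1-based order of the procedure in that operator's series
(``serial_index``), the procedure time in minutes, and three binary
outcomes — bladder-wall perforation, whether the lesion came out en bloc
(``en_bloc``; false means piecemeal resection), and whether detrusor
muscle was present in the specimen (``dm_present``).

The on-disk format is a plain UTF-8 CSV with a mandatory header::

    operator_id,seniority,serial_index,time_min,perforation,en_bloc,dm_present

Booleans are written as ``0``/``1`` and times with two decimals, so a
write-then-read round trip is the identity on valid logs.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

SENIORITIES = ("junior", "senior")

CSV_COLUMNS = (
    "operator_id",
    "seniority",
    "serial_index",
    "time_min",
    "perforation",
    "en_bloc",
    "dm_present",
)


class LogFormatError(ValueError):
    """A procedure-log file or record violates the schema.

    Carries the offending row number (1-based data row, header excluded)
    and field name when they are known.
    """

    def __init__(self, message: str, row: Optional[int] = None, fieldname: Optional[str] = None):
        self.row = row
        self.fieldname = fieldname
        prefix = ""
        if row is not None:
            prefix += f"row {row}"
        if fieldname is not None:
            prefix += (", " if prefix else "") + f"field {fieldname!r}"
        super().__init__(f"{prefix}: {message}" if prefix else message)


@dataclass(frozen=True)
class ProcedureRecord:
    """One resection event with its time and binary outcomes."""

    operator_id: str
    seniority: str
    serial_index: int
    time_min: float
    perforation: bool
    en_bloc: bool
    dm_present: bool

    def __post_init__(self) -> None:
        if self.seniority not in SENIORITIES:
            raise LogFormatError(
                f"seniority must be one of {SENIORITIES}, got {self.seniority!r}",
                fieldname="seniority",
            )
        if int(self.serial_index) != self.serial_index or self.serial_index < 1:
            raise LogFormatError(
                f"serial_index must be an integer >= 1, got {self.serial_index!r}",
                fieldname="serial_index",
            )
        if not self.time_min > 0:
            raise LogFormatError(
                f"time_min must be > 0, got {self.time_min!r}", fieldname="time_min"
            )


@dataclass
class ProcedureLog:
    """An ordered collection of procedure records.

    ``provenance`` is ``"simulated"`` or ``"observed"``; ``truth`` maps
    operator ids to their generative profiles and is populated only for
    simulated logs (used by parameter-recovery experiments).
    """

    records: list[ProcedureRecord]
    provenance: str = "observed"
    truth: Optional[Mapping[str, object]] = None

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProcedureLog):
            return NotImplemented
        return self.records == other.records and self.provenance == other.provenance

    def operators(self) -> list[str]:
        """Operator ids in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.operator_id, None)
        return list(seen)

    def seniority_of(self, operator_id: str) -> str:
        for r in self.records:
            if r.operator_id == operator_id:
                return r.seniority
        raise KeyError(operator_id)

    def select(self, group: str) -> "ProcedureLog":
        """Sub-log for a seniority group (``junior``/``senior``), ``all``,
        or a single operator id."""
        if group == "all":
            recs = list(self.records)
        elif group in SENIORITIES:
            recs = [r for r in self.records if r.seniority == group]
        else:
            recs = [r for r in self.records if r.operator_id == group]
        return ProcedureLog(recs, provenance=self.provenance, truth=self.truth)

    def to_frame(self):
        """The log as a pandas DataFrame (column order matches the CSV)."""
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "operator_id": r.operator_id,
                    "seniority": r.seniority,
                    "serial_index": r.serial_index,
                    "time_min": r.time_min,
                    "perforation": int(r.perforation),
                    "en_bloc": int(r.en_bloc),
                    "dm_present": int(r.dm_present),
                }
                for r in self.records
            ],
            columns=list(CSV_COLUMNS),
        )


@dataclass
class ValidationReport:
    """Outcome of checking a log against its invariants.

    ``ok`` is true iff ``issues`` is empty; each issue is
    ``(row_number, field, message)`` with a 1-based data row number
    (0 for log-level issues that have no single row).
    """

    issues: list[tuple[int, str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_log(log: ProcedureLog) -> ValidationReport:
    """Check every ProcedureLog invariant; report, never raise.

    Flags: non-positive times, duplicate ``(operator_id, serial_index)``
    pairs, operators whose serial indices are not consecutive from 1, and
    operators appearing under more than one seniority.
    """
    report = ValidationReport()
    seen_pairs: set[tuple[str, int]] = set()
    seniority_by_op: dict[str, str] = {}
    indices_by_op: dict[str, list[int]] = {}

    for rownum, r in enumerate(log.records, start=1):
        if not r.time_min > 0:
            report.issues.append((rownum, "time_min", f"non-positive time {r.time_min}"))
        key = (r.operator_id, r.serial_index)
        if key in seen_pairs:
            report.issues.append(
                (rownum, "serial_index", f"duplicate (operator_id, serial_index) {key}")
            )
        seen_pairs.add(key)
        prior = seniority_by_op.setdefault(r.operator_id, r.seniority)
        if prior != r.seniority:
            report.issues.append(
                (
                    rownum,
                    "seniority",
                    f"operator {r.operator_id!r} appears as both {prior!r} and {r.seniority!r}",
                )
            )
        indices_by_op.setdefault(r.operator_id, []).append(r.serial_index)

    for op, idx in indices_by_op.items():
        if sorted(idx) != list(range(1, len(idx) + 1)):
            report.issues.append(
                (
                    0,
                    "serial_index",
                    f"operator {op!r}: serial indices not consecutive from 1 "
                    f"(got {sorted(set(idx))})",
                )
            )
    return report


def _parse_bool(value: str, rownum: int, fieldname: str) -> bool:
    v = value.strip()
    if v in ("0", "1"):
        return v == "1"
    raise LogFormatError(f"expected 0 or 1, got {value!r}", row=rownum, fieldname=fieldname)


def read_procedure_log(path) -> ProcedureLog:
    """Read and validate a procedure-log CSV.

    Returns a log with ``provenance="observed"`` and row order preserved.
    Raises :class:`LogFormatError` naming the row and field on any schema
    violation (unknown/missing columns, non-positive time, non-boolean
    outcome flag, duplicate or non-consecutive serial indices).
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise LogFormatError("empty file, expected a header row")
        got = tuple(reader.fieldnames)
        if set(got) != set(CSV_COLUMNS):
            missing = sorted(set(CSV_COLUMNS) - set(got))
            extra = sorted(set(got) - set(CSV_COLUMNS))
            raise LogFormatError(
                f"bad header: missing columns {missing}, unknown columns {extra}"
            )
        records: list[ProcedureRecord] = []
        for rownum, row in enumerate(reader, start=1):
            try:
                serial_index = int(row["serial_index"])
            except ValueError:
                raise LogFormatError(
                    f"expected integer, got {row['serial_index']!r}",
                    row=rownum,
                    fieldname="serial_index",
                ) from None
            try:
                time_min = float(row["time_min"])
            except ValueError:
                raise LogFormatError(
                    f"expected number, got {row['time_min']!r}",
                    row=rownum,
                    fieldname="time_min",
                ) from None
            if not time_min > 0:
                raise LogFormatError(
                    f"non-positive time {time_min}", row=rownum, fieldname="time_min"
                )
            if row["seniority"] not in SENIORITIES:
                raise LogFormatError(
                    f"expected one of {SENIORITIES}, got {row['seniority']!r}",
                    row=rownum,
                    fieldname="seniority",
                )
            if serial_index < 1:
                raise LogFormatError(
                    f"serial_index must be >= 1, got {serial_index}",
                    row=rownum,
                    fieldname="serial_index",
                )
            records.append(
                ProcedureRecord(
                    operator_id=row["operator_id"],
                    seniority=row["seniority"],
                    serial_index=serial_index,
                    time_min=time_min,
                    perforation=_parse_bool(row["perforation"], rownum, "perforation"),
                    en_bloc=_parse_bool(row["en_bloc"], rownum, "en_bloc"),
                    dm_present=_parse_bool(row["dm_present"], rownum, "dm_present"),
                )
            )
    log = ProcedureLog(records, provenance="observed")
    report = validate_log(log)
    if not report.ok:
        rownum, fieldname, message = report.issues[0]
        raise LogFormatError(message, row=rownum or None, fieldname=fieldname)
    return log


def write_procedure_log(log: ProcedureLog, path) -> None:
    """Write a log as CSV: booleans as 0/1, times with two decimals."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in log.records:
            writer.writerow(
                [
                    r.operator_id,
                    r.seniority,
                    r.serial_index,
                    f"{r.time_min:.2f}",
                    int(r.perforation),
                    int(r.en_bloc),
                    int(r.dm_present),
                ]
            )


def write_truth(truth: Mapping[str, object], path) -> None:
    """Persist generative profiles alongside a simulated log (JSON)."""
    from dataclasses import asdict, is_dataclass

    payload = {
        op: (asdict(p) if is_dataclass(p) else p) for op, p in truth.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
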