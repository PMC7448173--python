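"""Reading, writing and validating the delimited-text log and formulary formats.

Vendor export dialects are proprietary, so the package defines an open CSV
dialect (UTF-8, header row) and a small column-map config through which other
delimited dialects can be adapted.  Unparseable rows are quarantined with a
reason, never silently dropped.

Event-log header::

    timestamp,device_id,module_id,module_type,profile,sequence_id,event_type,
    medication_name,therapy,dose_value,dose_unit,concentration_value

Formulary header::

    profile,core_name,therapy_name,tallman_form,soft_min,soft_max,hard_min,
    hard_max,conc_min,conc_max,standard_concentrations

Timestamps are ISO-8601 local time at one-second resolution; single-facility
logs need no time-zone arithmetic.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import IO, Union

from .model import (
    ALERTISH_EVENTS,
    EventLog,
    EventRecord,
    EventType,
    Formulary,
    MedicationEntry,
    ModuleType,
    QuarantinedRow,
    RESOLUTION_EVENTS,
    ValidationReport,
)

Source = Union[str, Path, IO[str]]

EVENT_LOG_COLUMNS = (
    "timestamp",
    "device_id",
    "module_id",
    "module_type",
    "profile",
    "sequence_id",
    "event_type",
    "medication_name",
    "therapy",
    "dose_value",
    "dose_unit",
    "concentration_value",
)

FORMULARY_COLUMNS = (
    "profile",
    "core_name",
    "therapy_name",
    "tallman_form",
    "soft_min",
    "soft_max",
    "hard_min",
    "hard_max",
    "conc_min",
    "conc_max",
    "standard_concentrations",
)


class DialectError(ValueError):
    """Fatal configuration problem: missing mandatory column, bad delimiter."""


@dataclass(slots=True)
class Dialect:
    """Delimiter + column-name mapping from a foreign header to the open one.

    ``column_map`` maps *our* field names to the source file's column names;
    identity by default.
    """

    delimiter: str = ","
    column_map: dict[str, str] = field(default_factory=dict)

    def source_column(self, name: str) -> str:
        return self.column_map.get(name, name)


def _open(source: Source, mode: str = "r"):
    if isinstance(source, (str, Path)):
        return open(source, mode, encoding="utf-8", newline=""), True
    return source, False


def _parse_float(text: str) -> float | None:
    text = text.strip()
    if not text:
        return None
    return float(text)


def read_event_log(source: Source, dialect: Dialect | None = None) -> EventLog:
    """Parse a delimited event log; quarantine malformed rows.

    Records are returned sorted by ``(device_id, module_id, timestamp)`` with
    file order breaking ties, so parsing is insensitive to input row order.

    Raises :class:`DialectError` if a mandatory column is absent from the
    header.  Rows with malformed timestamps, unknown enum values or invalid
    numbers are quarantined on the returned log with row index and reason.
    """
    dialect = dialect or Dialect()
    fh, close = _open(source)
    try:
        reader = csv.DictReader(fh, delimiter=dialect.delimiter)
        header = reader.fieldnames or []
        for col in EVENT_LOG_COLUMNS:
            if dialect.source_column(col) not in header:
                raise DialectError(
                    f"mandatory column {dialect.source_column(col)!r} missing "
                    f"from header {header!r}"
                )
        records: list[EventRecord] = []
        quarantined: list[QuarantinedRow] = []
        for idx, row in enumerate(reader):
            get = lambda c: (row.get(dialect.source_column(c)) or "").strip()
            try:
                rec = EventRecord(
                    timestamp=datetime.fromisoformat(get("timestamp")),
                    device_id=get("device_id"),
                    module_id=get("module_id"),
                    module_type=ModuleType(get("module_type")),
                    profile=get("profile"),
                    sequence_id=get("sequence_id"),
                    event_type=EventType(get("event_type")),
                    medication_name=get("medication_name"),
                    therapy=get("therapy"),
                    dose_value=_parse_float(get("dose_value")),
                    dose_unit=get("dose_unit"),
                    concentration_value=_parse_float(get("concentration_value")),
                )
            except (ValueError, KeyError) as exc:
                quarantined.append(QuarantinedRow(idx, dict(row), str(exc)))
                continue
            records.append(rec)
    finally:
        if close:
            fh.close()
    log = EventLog(records, {"source": str(source)}, quarantined)
    return log.sorted()


def _fmt_num(value: float | None) -> str:
    if value is None:
        return ""
    # str(float) is the shortest round-trip repr; ints stay readable
    return str(value)


def write_event_log(log: EventLog, target: Source, dialect: Dialect | None = None) -> None:
    """Write the open CSV dialect; inverse of :func:`read_event_log`."""
    dialect = dialect or Dialect()
    fh, close = _open(target, "w")
    try:
        writer = csv.writer(fh, delimiter=dialect.delimiter)
        writer.writerow([dialect.source_column(c) for c in EVENT_LOG_COLUMNS])
        for r in log.records:
            writer.writerow(
                [
                    r.timestamp.isoformat(sep=" "),
                    r.device_id,
                    r.module_id,
                    r.module_type.value,
                    r.profile,
                    r.sequence_id,
                    r.event_type.value,
                    r.medication_name,
                    r.therapy,
                    _fmt_num(r.dose_value),
                    r.dose_unit,
                    _fmt_num(r.concentration_value),
                ]
            )
    finally:
        if close:
            fh.close()


class FormularyError(ValueError):
    """Fatal formulary validation problem (duplicate key, oversize name)."""


def read_formulary(source: Source, delimiter: str = ",") -> Formulary:
    """Parse a formulary CSV.

    Entries whose name fields exceed the 20-character pump cap, or whose
    (profile, core_name, therapy_name) key repeats, raise
    :class:`FormularyError` naming the offending row.
    """
    fh, close = _open(source)
    try:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        for col in FORMULARY_COLUMNS:
            if col not in header:
                raise DialectError(f"mandatory column {col!r} missing from header")
        formulary = Formulary()
        for idx, row in enumerate(reader):
            get = lambda c: (row.get(c) or "").strip()
            concs = tuple(
                float(x) for x in get("standard_concentrations").split(";") if x.strip()
            )
            try:
                entry = MedicationEntry(
                    core_name=get("core_name"),
                    therapy_name=get("therapy_name"),
                    tallman_form=get("tallman_form"),
                    profile=get("profile"),
                    soft_min=_parse_float(get("soft_min")),
                    soft_max=_parse_float(get("soft_max")),
                    hard_min=_parse_float(get("hard_min")),
                    hard_max=_parse_float(get("hard_max")),
                    conc_min=_parse_float(get("conc_min")),
                    conc_max=_parse_float(get("conc_max")),
                    standard_concentrations=concs,
                )
                formulary.add(entry)
            except ValueError as exc:
                raise FormularyError(f"row {idx}: {exc}") from exc
    finally:
        if close:
            fh.close()
    if len(formulary) and not formulary.profiles:
        raise FormularyError("formulary must declare at least one profile")
    return formulary


def write_formulary(formulary: Formulary, target: Source, delimiter: str = ",") -> None:
    fh, close = _open(target, "w")
    try:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(FORMULARY_COLUMNS)
        for e in formulary:
            writer.writerow(
                [
                    e.profile,
                    e.core_name,
                    e.therapy_name,
                    e.tallman_form,
                    _fmt_num(e.soft_min),
                    _fmt_num(e.soft_max),
                    _fmt_num(e.hard_min),
                    _fmt_num(e.hard_max),
                    _fmt_num(e.conc_min),
                    _fmt_num(e.conc_max),
                    ";".join(str(c) for c in e.standard_concentrations),
                ]
            )
    finally:
        if close:
            fh.close()


def _count_inversions(values: list) -> int:
    """Number of out-of-order pairs (i < j with values[i] > values[j])."""
    # merge-sort count; O(n log n), matches the brute-force pairwise definition
    def sort(a: list) -> tuple[list, int]:
        if len(a) <= 1:
            return a, 0
        mid = len(a) // 2
        left, nl = sort(a[:mid])
        right, nr = sort(a[mid:])
        merged, inv, i, j = [], nl + nr, 0, 0
        while i < len(left) and j < len(right):
            if left[i] <= right[j]:
                merged.append(left[i])
                i += 1
            else:
                merged.append(right[j])
                j += 1
                inv += len(left) - i
        merged.extend(left[i:])
        merged.extend(right[j:])
        return merged, inv

    return sort(list(values))[1]


def validate_log(log: EventLog) -> ValidationReport:
    """Report anomalies without mutating the log.

    Orphan resolutions, duplicate sequence ids across device+module pairs, and
    per-module timestamp inversions (in the order records are held) are counted
    with exemplar record indices.
    """
    report = ValidationReport(n_records=len(log))
    seq_alerts: dict[tuple[str, str, str], bool] = {}
    seq_owner: dict[str, set[tuple[str, str]]] = {}
    by_module: dict[tuple[str, str], list[datetime]] = {}
    orphan_rows: list[int] = []

    for idx, r in enumerate(log.records):
        mod = (r.device_id, r.module_id)
        by_module.setdefault(mod, []).append(r.timestamp)
        if r.sequence_id:
            seq_owner.setdefault(r.sequence_id, set()).add(mod)
            key = (r.device_id, r.module_id, r.sequence_id)
            if r.event_type in ALERTISH_EVENTS:
                seq_alerts[key] = True
            else:
                seq_alerts.setdefault(key, False)

    for idx, r in enumerate(log.records):
        if r.event_type in RESOLUTION_EVENTS:
            key = (r.device_id, r.module_id, r.sequence_id)
            if not r.sequence_id or not seq_alerts.get(key, False):
                report.orphan_resolutions += 1
                orphan_rows.append(idx)

    dup_ids = sorted(s for s, owners in seq_owner.items() if len(owners) > 1)
    report.duplicate_sequence_ids = len(dup_ids)

    report.time_regressions = sum(
        _count_inversions(ts) for ts in by_module.values()
    )
    report.exemplars = {
        "orphan_resolutions": orphan_rows[:10],
        "duplicate_sequence_ids": dup_ids[:10],
    }
    return report
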