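"""Core data model for smart-pump DERS event logs and medication libraries.

A dose-error-reduction-software (DERS) log is a time-stamped stream of
programming events emitted by modular infusion pumps: medication selections,
soft/hard/concentration limit alerts, overrides, reprograms, cancellations and
infusion starts.  Events belonging to one alert episode — from first alert to
resolution — share a *sequence id*.  Timestamps have one-second resolution.

A medication library (formulary) is the per-facility drug list loaded on the
pumps, organised by care-area *profile*, with a 20-character cap on the core
medication name and a further 20-character therapy line below it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Iterator, Mapping, Optional

MAX_NAME_CHARS = 20  # pump display/entry cap for core name and therapy line


class ModuleType(str, enum.Enum):
    LARGE_VOLUME = "LARGE_VOLUME"
    SYRINGE = "SYRINGE"
    PCA = "PCA"


class EventType(str, enum.Enum):
    PROGRAM_SELECT = "PROGRAM_SELECT"
    SOFT_LIMIT_ALERT = "SOFT_LIMIT_ALERT"
    HARD_LIMIT_ALERT = "HARD_LIMIT_ALERT"
    CONC_LIMIT_ALERT = "CONC_LIMIT_ALERT"
    OVERRIDE = "OVERRIDE"
    REPROGRAM = "REPROGRAM"
    CANCEL = "CANCEL"
    INFUSION_START = "INFUSION_START"
    BASIC_INFUSION_START = "BASIC_INFUSION_START"
    CALC_START = "CALC_START"
    OTHER_ALERT = "OTHER_ALERT"


#: Event types that open or belong to an alert episode (carry a sequence id).
ALERTISH_EVENTS = frozenset(
    {
        EventType.PROGRAM_SELECT,
        EventType.SOFT_LIMIT_ALERT,
        EventType.HARD_LIMIT_ALERT,
        EventType.CONC_LIMIT_ALERT,
        EventType.OTHER_ALERT,
    }
)

#: Event types that resolve an episode.
RESOLUTION_EVENTS = frozenset(
    {EventType.OVERRIDE, EventType.REPROGRAM, EventType.CANCEL}
)

#: Start events that never record a medication name (library bypass modes).
NAMELESS_STARTS = frozenset(
    {EventType.BASIC_INFUSION_START, EventType.CALC_START}
)


@dataclass(slots=True)
class EventRecord:
    """One time-stamped pump event."""

    timestamp: datetime
    device_id: str
    module_id: str
    module_type: ModuleType
    profile: str
    sequence_id: str
    event_type: EventType
    medication_name: str = ""
    therapy: str = ""
    dose_value: Optional[float] = None
    dose_unit: str = ""
    concentration_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.event_type in NAMELESS_STARTS and self.medication_name:
            raise ValueError(
                f"{self.event_type.value} records cannot carry a medication "
                f"name (basic/calculator modes do not record it)"
            )
        if self.dose_value is not None and self.dose_value < 0:
            raise ValueError("dose_value must be nonnegative")
        if self.concentration_value is not None and self.concentration_value < 0:
            raise ValueError("concentration_value must be nonnegative")


@dataclass(slots=True)
class QuarantinedRow:
    """An input row that failed to parse, retained with its reason."""

    row_index: int
    raw: Mapping[str, str]
    reason: str


@dataclass
class EventLog:
    """An ordered collection of :class:`EventRecord` plus provenance.

    ``records`` are kept in the order given; :func:`pumpguard.io.read_event_log`
    sorts them by ``(device_id, module_id, timestamp)`` with file order breaking
    ties.
    """

    records: list[EventRecord] = field(default_factory=list)
    source_meta: dict = field(default_factory=dict)
    quarantined: list[QuarantinedRow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[EventRecord]:
        return iter(self.records)

    def sorted(self) -> "EventLog":
        """Return a copy sorted by (device, module, timestamp); stable in ties."""
        recs = sorted(
            self.records, key=lambda r: (r.device_id, r.module_id, r.timestamp)
        )
        return EventLog(recs, dict(self.source_meta), list(self.quarantined))


@dataclass(slots=True)
class MedicationEntry:
    """One medication set-up in the DERS library.

    ``tallman_form`` preserves the selective-capitalisation (TALLman) spelling,
    e.g. ``FLUconazole``; it must equal ``core_name`` once case is folded.
    Empty ``standard_concentrations`` together with concentration limits means a
    "wildcard"/custom concentration entry.
    """

    core_name: str
    therapy_name: str = ""
    tallman_form: str = ""
    profile: str = "DEFAULT"
    soft_min: Optional[float] = None
    soft_max: Optional[float] = None
    hard_min: Optional[float] = None
    hard_max: Optional[float] = None
    conc_min: Optional[float] = None
    conc_max: Optional[float] = None
    standard_concentrations: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(self.core_name) > MAX_NAME_CHARS:
            raise ValueError(
                f"core_name {self.core_name!r} exceeds {MAX_NAME_CHARS} characters"
            )
        if len(self.therapy_name) > MAX_NAME_CHARS:
            raise ValueError(
                f"therapy_name {self.therapy_name!r} exceeds "
                f"{MAX_NAME_CHARS} characters"
            )
        if self.tallman_form and self.tallman_form.casefold() != self.core_name.casefold():
            raise ValueError(
                f"tallman_form {self.tallman_form!r} is not a recapitalisation "
                f"of core_name {self.core_name!r}"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.profile, self.core_name, self.therapy_name)


class Formulary:
    """Medication entries keyed by (profile, core_name, therapy_name)."""

    def __init__(self, entries: Iterable[MedicationEntry] = ()) -> None:
        self._entries: dict[tuple[str, str, str], MedicationEntry] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: MedicationEntry) -> None:
        if entry.key in self._entries:
            raise ValueError(f"duplicate formulary key {entry.key!r}")
        self._entries[entry.key] = entry

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[MedicationEntry]:
        return iter(self._entries.values())

    def __contains__(self, key: tuple[str, str, str]) -> bool:
        return key in self._entries

    def get(self, profile: str, core_name: str, therapy_name: str = "") -> Optional[MedicationEntry]:
        return self._entries.get((profile, core_name, therapy_name))

    @property
    def profiles(self) -> list[str]:
        return sorted({e.profile for e in self})

    def core_names(self, profile: Optional[str] = None) -> list[str]:
        """Unique core names, optionally restricted to one care-area profile."""
        names = {
            e.core_name
            for e in self
            if profile is None or e.profile == profile
        }
        return sorted(names)


@dataclass(slots=True)
class ValidationReport:
    """Anomaly counts for an event log; reporting only, never mutating.

    ``orphan_resolutions``: OVERRIDE/REPROGRAM/CANCEL records whose sequence id
    matches no alert/selection record on the same device+module.
    ``duplicate_sequence_ids``: sequence ids reused across distinct
    device+module pairs.
    ``time_regressions``: out-of-order timestamp pairs (inversions) within a
    device+module, in the order the records are held.
    """

    n_records: int = 0
    orphan_resolutions: int = 0
    duplicate_sequence_ids: int = 0
    time_regressions: int = 0
    exemplars: dict = field(default_factory=dict)

    @property
    def clean(self) -> bool:
        return (
            self.orphan_resolutions == 0
            and self.duplicate_sequence_ids == 0
            and self.time_regressions == 0
        )
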