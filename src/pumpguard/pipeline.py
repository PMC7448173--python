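"""Near-miss detection pipeline: sequences, correction pairs, cause labels, summaries.

The analysis walks a validated event log through four stages:

1. **group** — records sharing a sequence id on one device+module form an
   :class:`EventSequence`; the terminal event fixes its outcome.
2. **pair** — each cancelled sequence is matched to the next program on the
   same device whose first event falls within a pairing window (default 120 s,
   chosen because observed correction latencies top out near two minutes).
   A cancellation rapidly followed by a second program is the signature of a
   user-initiated "good save".
3. **classify** — a first-match decision ladder assigns one of six exclusive
   cancellation causes (concentration-limit breach, calculator bail-out,
   wrong channel, wrong medication, wrong dose, indeterminate).
4. **summarise** — alert-mix, cause-mix, decision-time, dose-error-factor and
   library-compliance statistics, with every percentage carried next to the
   counts it was computed from.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Optional, Sequence, Union

from ._stats import describe, pct
from .lasa import PositionClass, divergence_position, normalize_name
from .model import EventLog, EventRecord, EventType, Formulary, ModuleType
from .units import UnitError, convert, doses_equal

DEFAULT_PAIRING_WINDOW_S = 120
DEFAULT_EXTREME_FACTOR_THRESHOLD = 100.0
DOSE_EQUALITY_REL_TOL = 1e-6


class Outcome(str, enum.Enum):
    OVERRIDDEN = "OVERRIDDEN"
    REPROGRAMMED = "REPROGRAMMED"
    CANCELLED = "CANCELLED"
    STARTED = "STARTED"
    UNRESOLVED = "UNRESOLVED"


_TERMINAL_OUTCOME = {
    EventType.OVERRIDE: Outcome.OVERRIDDEN,
    EventType.REPROGRAM: Outcome.REPROGRAMMED,
    EventType.CANCEL: Outcome.CANCELLED,
    EventType.INFUSION_START: Outcome.STARTED,
    EventType.BASIC_INFUSION_START: Outcome.STARTED,
    EventType.CALC_START: Outcome.STARTED,
}


class CauseLabel(str, enum.Enum):
    """The six exclusive cancellation-cause categories."""

    INCORRECT_MEDICATION = "INCORRECT_MEDICATION"
    WRONG_DOSE = "WRONG_DOSE"
    INDETERMINATE = "INDETERMINATE"
    WRONG_CHANNEL = "WRONG_CHANNEL"
    DOSE_CANCELLED_CALC = "DOSE_CANCELLED_CALC"
    CONC_LIMIT_BREACH = "CONC_LIMIT_BREACH"


class TimeConvention(str, enum.Enum):
    """Which two log anchors bound a clinician decision time."""

    CANCEL_TO_CORRECT = "CANCEL_TO_CORRECT"
    SELECT_TO_CANCEL = "SELECT_TO_CANCEL"


@dataclass
class EventSequence:
    """One alert episode: events sharing a sequence id on one device+module."""

    sequence_id: str
    device_id: str
    module_id: str
    events: list[EventRecord]

    def __post_init__(self) -> None:
        self.events.sort(key=lambda r: r.timestamp)

    @property
    def outcome(self) -> Outcome:
        return _TERMINAL_OUTCOME.get(self.events[-1].event_type, Outcome.UNRESOLVED)

    @property
    def first_time(self) -> datetime:
        return self.events[0].timestamp

    @property
    def last_time(self) -> datetime:
        return self.events[-1].timestamp

    @property
    def module_type(self) -> ModuleType:
        return self.events[0].module_type

    def _program(self) -> Optional[EventRecord]:
        for r in self.events:
            if r.event_type in (
                EventType.PROGRAM_SELECT,
                EventType.INFUSION_START,
                EventType.CALC_START,
                EventType.BASIC_INFUSION_START,
            ):
                return r
        return self.events[0]

    @property
    def medication_name(self) -> str:
        rec = self._program()
        return rec.medication_name if rec else ""

    @property
    def dose(self) -> tuple[Optional[float], str]:
        rec = self._program()
        return (rec.dose_value, rec.dose_unit) if rec else (None, "")

    @property
    def concentration(self) -> Optional[float]:
        rec = self._program()
        return rec.concentration_value if rec else None

    @property
    def select_time(self) -> Optional[datetime]:
        for r in self.events:
            if r.event_type is EventType.PROGRAM_SELECT:
                return r.timestamp
        return None

    @property
    def cancel_time(self) -> Optional[datetime]:
        for r in reversed(self.events):
            if r.event_type is EventType.CANCEL:
                return r.timestamp
        return None

    @property
    def confirmation_time(self) -> datetime:
        """Program-confirmation anchor: the start event if present, else last event."""
        for r in self.events:
            if r.event_type in (
                EventType.INFUSION_START,
                EventType.CALC_START,
                EventType.BASIC_INFUSION_START,
            ):
                return r.timestamp
        return self.last_time

    def has_event(self, event_type: EventType) -> bool:
        return any(r.event_type is event_type for r in self.events)


def group_sequences(log: Union[EventLog, Iterable[EventRecord]]) -> list[EventSequence]:
    """Group records into alert sequences.

    Records sharing a sequence id on the same device+module form one sequence
    (identical ids on different devices therefore split cleanly); records with
    no sequence id each form a singleton.  Sequences come back ordered by
    (device, module, first event time) — deterministic regardless of input
    record order.
    """
    records = log.records if isinstance(log, EventLog) else list(log)
    buckets: dict[tuple[str, str, str], list[EventRecord]] = {}
    singletons: list[EventRecord] = []
    for r in records:
        if r.sequence_id:
            buckets.setdefault((r.device_id, r.module_id, r.sequence_id), []).append(r)
        else:
            singletons.append(r)
    sequences = [
        EventSequence(seq_id, dev, mod, recs)
        for (dev, mod, seq_id), recs in buckets.items()
    ]
    sequences.extend(
        EventSequence("", r.device_id, r.module_id, [r]) for r in singletons
    )
    sequences.sort(key=lambda s: (s.device_id, s.module_id, s.first_time, s.sequence_id))
    return sequences


@dataclass
class CorrectionPair:
    """A cancelled program matched (or not) to its rapid replacement."""

    cancelled: EventSequence
    replacement: Optional[EventSequence] = None
    latency_s: Optional[int] = None
    cause: Optional[CauseLabel] = None
    dose_error_factor: Optional[float] = None
    lasa_position: Optional[PositionClass] = None
    flags: list[str] = field(default_factory=list)


def pair_cancellations(
    sequences: Sequence[EventSequence],
    window_s: int = DEFAULT_PAIRING_WINDOW_S,
) -> list[CorrectionPair]:
    """Match every cancelled sequence with its replacement program, if any.

    The replacement is the next sequence on the *same device* whose first event
    falls within ``window_s`` seconds after the cancellation; the same module
    is preferred on ties, but a different module on the same device is
    admissible — a wrong-channel correction (PCA medication initially loaded in
    a syringe driver) is only observable across modules.  Latency is the
    replacement's program-confirmation time minus the cancellation time; a
    negative latency (clock regression) rejects the match and flags the pair.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    by_device: dict[str, list[EventSequence]] = {}
    for s in sequences:
        by_device.setdefault(s.device_id, []).append(s)
    for seqs in by_device.values():
        seqs.sort(key=lambda s: (s.first_time, s.sequence_id))

    pairs: list[CorrectionPair] = []
    for dev, seqs in sorted(by_device.items()):
        for idx, s in enumerate(seqs):
            if s.outcome is not Outcome.CANCELLED:
                continue
            cancel_t = s.cancel_time or s.last_time
            pair = CorrectionPair(cancelled=s)
            best: Optional[EventSequence] = None
            for cand in seqs[idx + 1 :]:
                if cand is s:
                    continue
                delta = (cand.first_time - cancel_t).total_seconds()
                if delta < 0:
                    continue
                if delta > window_s:
                    break
                if best is None:
                    best = cand
                elif cand.first_time == best.first_time and (
                    cand.module_id == s.module_id and best.module_id != s.module_id
                ):
                    best = cand  # same-module candidate wins exact time ties
            if best is not None:
                latency = (best.confirmation_time - cancel_t).total_seconds()
                if latency < 0:
                    pair.flags.append("negative_latency_rejected")
                else:
                    pair.replacement = best
                    pair.latency_s = int(round(latency))
                    if best.module_id != s.module_id:
                        pair.flags.append("cross_module")
            pairs.append(pair)
    return pairs


def decision_time(
    pair: CorrectionPair,
    convention: TimeConvention = TimeConvention.CANCEL_TO_CORRECT,
) -> Optional[int]:
    """Clinician decision time in whole seconds under the chosen convention.

    CANCEL_TO_CORRECT (default): replacement confirmation − cancellation.
    SELECT_TO_CANCEL: cancellation − erroneous program selection.
    Returns None when an endpoint is missing; such pairs are excluded from
    statistics rather than imputed.
    """
    convention = TimeConvention(convention)
    cancel_t = pair.cancelled.cancel_time
    if convention is TimeConvention.CANCEL_TO_CORRECT:
        if pair.replacement is None or cancel_t is None:
            return None
        delta = (pair.replacement.confirmation_time - cancel_t).total_seconds()
    else:
        select_t = pair.cancelled.select_time
        if select_t is None or cancel_t is None:
            return None
        delta = (cancel_t - select_t).total_seconds()
    return int(round(delta)) if delta >= 0 else None


def dose_error_factor(pair: CorrectionPair) -> Optional[float]:
    """Cancelled dose over corrected dose after unit normalisation.

    A factor above 1 is a potential overdose ("times the corrected dose"),
    below 1 a potential underdose; both are retained.  Returns None (and flags
    the pair) when a dose or unit is missing, units are dimensionally
    incompatible with no concentration to bridge them, or the corrected dose
    is zero.
    """
    if pair.replacement is None:
        return None
    dose_c, unit_c = pair.cancelled.dose
    dose_r, unit_r = pair.replacement.dose
    if dose_c is None or dose_r is None or not unit_c.strip() or not unit_r.strip():
        pair.flags.append("dose_factor_missing_data")
        return None
    try:
        dose_c_in_r = convert(dose_c, unit_c, unit_r)
    except UnitError:
        pair.flags.append("dose_factor_incompatible_units")
        return None
    if dose_r == 0:
        pair.flags.append("dose_factor_zero_corrected_dose")
        return None
    return dose_c_in_r / dose_r


def classify_cause(
    pair: CorrectionPair,
    formulary: Optional[Formulary] = None,
    name_normalizer=None,
) -> CauseLabel:
    """Assign a cancellation cause; first matching ladder rule wins.

    1. cancelled sequence saw a concentration-limit alert → CONC_LIMIT_BREACH
    2. replacement is a drug-calculator start → DOSE_CANCELLED_CALC
    3. same medication, replacement module swapped PCA↔syringe → WRONG_CHANNEL
    4. replacement carries a different medication name → INCORRECT_MEDICATION
    5. same medication, dose or concentration differs beyond unit-normalised
       equality (relative tolerance 1e-6) → WRONG_DOSE
    6. otherwise (no replacement, nameless replacement, or no detectable
       delta) → INDETERMINATE

    Sets ``pair.cause`` and, where applicable, ``pair.lasa_position`` (rule 4)
    and ``pair.dose_error_factor`` (rule 5).
    """
    if name_normalizer is None:
        name_normalizer = lambda n: normalize_name(n, formulary=formulary)

    def decide() -> CauseLabel:
        if pair.cancelled.has_event(EventType.CONC_LIMIT_ALERT):
            return CauseLabel.CONC_LIMIT_BREACH
        repl = pair.replacement
        if repl is None:
            return CauseLabel.INDETERMINATE
        if repl.has_event(EventType.CALC_START):
            return CauseLabel.DOSE_CANCELLED_CALC
        name_c = name_normalizer(pair.cancelled.medication_name)
        name_r = name_normalizer(repl.medication_name)
        if not name_r:
            pair.flags.append("replacement_without_medication_name")
            return CauseLabel.INDETERMINATE
        if name_c == name_r and {pair.cancelled.module_type, repl.module_type} == {
            ModuleType.PCA,
            ModuleType.SYRINGE,
        }:
            return CauseLabel.WRONG_CHANNEL
        if name_c and name_c != name_r:
            pair.lasa_position = divergence_position(
                pair.cancelled.medication_name, repl.medication_name
            )
            return CauseLabel.INCORRECT_MEDICATION
        dose_c, unit_c = pair.cancelled.dose
        dose_r, unit_r = repl.dose
        same_dose = doses_equal(dose_c, unit_c, dose_r, unit_r, DOSE_EQUALITY_REL_TOL)
        conc_c, conc_r = pair.cancelled.concentration, repl.concentration
        conc_differs = (
            conc_c is not None
            and conc_r is not None
            and abs(conc_c - conc_r) > DOSE_EQUALITY_REL_TOL * max(abs(conc_c), abs(conc_r))
        )
        if same_dose is False or conc_differs:
            pair.dose_error_factor = dose_error_factor(pair)
            return CauseLabel.WRONG_DOSE
        return CauseLabel.INDETERMINATE

    pair.cause = decide()
    return pair.cause


@dataclass(slots=True)
class CauseStats:
    """One cancellation-cause row: count and its two percentage bases."""

    cause: CauseLabel
    count: int
    pct_of_cancellations: Optional[float]  # None for conc-limit breaches (N/A)
    pct_of_alerts: Optional[float]


@dataclass
class CancellationSummary:
    """Per-cause counts/percentages plus decision-time and dose-factor stats.

    Concentration-limit breaches are counted but excluded from the
    cancellation denominator: on the pump they surface as reprogram
    (hard-limit) alerts, not as cancelled-infusion alerts, so their share of
    cancellations is not applicable.
    """

    by_cause: dict[CauseLabel, CauseStats]
    total_cancellations: int  # cancellations excluding conc-limit breaches
    total_alerts: Optional[int]
    decision_time_stats: dict[CauseLabel, dict]
    dose_factor_stats: dict
    extreme_factor_threshold: float = DEFAULT_EXTREME_FACTOR_THRESHOLD

    @classmethod
    def from_counts(
        cls,
        counts: dict[CauseLabel, int],
        total_alerts: Optional[int] = None,
        decision_time_stats: Optional[dict] = None,
        dose_factor_stats: Optional[dict] = None,
        extreme_factor_threshold: float = DEFAULT_EXTREME_FACTOR_THRESHOLD,
    ) -> "CancellationSummary":
        full = {c: int(counts.get(c, 0)) for c in CauseLabel}
        total = sum(n for c, n in full.items() if c is not CauseLabel.CONC_LIMIT_BREACH)
        by_cause = {}
        for c, n in full.items():
            of_cancel = (
                None
                if c is CauseLabel.CONC_LIMIT_BREACH or total == 0
                else pct(n, total)
            )
            of_alerts = pct(n, total_alerts) if total_alerts else None
            by_cause[c] = CauseStats(c, n, of_cancel, of_alerts)
        return cls(
            by_cause=by_cause,
            total_cancellations=total,
            total_alerts=total_alerts,
            decision_time_stats=decision_time_stats or {},
            dose_factor_stats=dose_factor_stats or {},
            extreme_factor_threshold=extreme_factor_threshold,
        )


def summarize_cancellations(
    pairs: Sequence[CorrectionPair],
    total_alerts: Optional[int] = None,
    convention: TimeConvention = TimeConvention.CANCEL_TO_CORRECT,
    extreme_factor_threshold: float = DEFAULT_EXTREME_FACTOR_THRESHOLD,
) -> CancellationSummary:
    """Tabulate classified correction pairs.

    Decision-time statistics (mean, SD, median, min, max) are computed per
    cause over pairs where the convention's endpoints exist; dose-error-factor
    statistics cover wrong-dose pairs with a computable factor, reporting the
    overdose convention ("times the corrected dose") plus the count above the
    extreme threshold and the underdose (<1) count separately.
    """
    counts: dict[CauseLabel, int] = {c: 0 for c in CauseLabel}
    times: dict[CauseLabel, list[int]] = {c: [] for c in CauseLabel}
    factors: list[float] = []
    for p in pairs:
        cause = p.cause or CauseLabel.INDETERMINATE
        counts[cause] += 1
        t = decision_time(p, convention)
        if t is not None:
            times[cause].append(t)
        if cause is CauseLabel.WRONG_DOSE and p.dose_error_factor is not None:
            factors.append(p.dose_error_factor)

    dt_stats = {c: describe(v) for c, v in times.items() if v}
    df = describe(factors)
    df["n_extreme"] = sum(1 for f in factors if f > extreme_factor_threshold)
    df["n_underdose"] = sum(1 for f in factors if f < 1.0)
    return CancellationSummary.from_counts(
        counts,
        total_alerts=total_alerts,
        decision_time_stats=dt_stats,
        dose_factor_stats=df,
        extreme_factor_threshold=extreme_factor_threshold,
    )


@dataclass
class AlertMixSummary:
    """Alert counts by type: hard-limit reprograms, soft-limit overrides,
    cancelled infusions, and all other alerts."""

    hard: int
    soft: int
    cancelled: int
    other: int
    percentages: dict[str, Optional[float]]

    @property
    def total(self) -> int:
        return self.hard + self.soft + self.cancelled + self.other

    @classmethod
    def from_counts(cls, hard: int, soft: int, cancelled: int, other: int) -> "AlertMixSummary":
        total = hard + soft + cancelled + other
        pcts = {
            k: (pct(v, total) if total else None)
            for k, v in (("hard", hard), ("soft", soft), ("cancelled", cancelled), ("other", other))
        }
        return cls(hard=hard, soft=soft, cancelled=cancelled, other=other, percentages=pcts)


def summarize_alerts(
    log: Union[EventLog, Sequence[EventSequence]],
) -> AlertMixSummary:
    """Count alert sequences by type.

    A sequence containing a hard-limit or concentration-limit alert counts as a
    hard-limit ("reprogram limit") alert — concentration breaches surface
    there, not under cancelled infusions.  Otherwise a cancelled outcome counts
    as a cancelled infusion, a soft-limit alert as an override alert, and any
    remaining alert-bearing sequence as "other".  Clean program/start sequences
    are not alerts and do not contribute.
    """
    sequences = (
        group_sequences(log) if isinstance(log, EventLog) else log
    )
    hard = soft = cancelled = other = 0
    for s in sequences:
        if s.has_event(EventType.HARD_LIMIT_ALERT) or s.has_event(EventType.CONC_LIMIT_ALERT):
            hard += 1
        elif s.outcome is Outcome.CANCELLED:
            cancelled += 1
        elif s.has_event(EventType.SOFT_LIMIT_ALERT):
            soft += 1
        elif s.has_event(EventType.OTHER_ALERT):
            other += 1
    return AlertMixSummary.from_counts(hard, soft, cancelled, other)


@dataclass(slots=True)
class ComplianceStats:
    """Share of infusions started through the DERS library."""

    library_starts: int
    total_starts: int
    compliance_pct: float


def compute_compliance(log: Union[EventLog, Iterable[EventRecord]]) -> ComplianceStats:
    """Library starts over all starts (library + basic mL/h + calculator).

    Raises ValueError when the log contains no start events at all — a
    compliance fraction is undefined there, not zero.
    """
    records = log.records if isinstance(log, EventLog) else log
    library = basic = calc = 0
    for r in records:
        if r.event_type is EventType.INFUSION_START:
            library += 1
        elif r.event_type is EventType.BASIC_INFUSION_START:
            basic += 1
        elif r.event_type is EventType.CALC_START:
            calc += 1
    total = library + basic + calc
    if total == 0:
        raise ValueError("no infusion starts in log; compliance undefined")
    return ComplianceStats(library, total, pct(library, total))
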