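"""Assemble analysis outputs into report tables (CSV / markdown / JSON).

Every percentage is emitted next to the raw counts it was computed from, so
any number in a report can be re-derived.  Quotients are always the exact
round-half-up values at two decimals; published variants that disagree with
exact division are a documentation matter, never silently matched.
"""

from __future__ import annotations

import io as _io
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .io import read_event_log, read_formulary, validate_log
from .lasa import CharCountReport, Position, PositionSummary, char_count_distribution, summarize_positions
from .model import EventLog, Formulary
from .pipeline import (
    AlertMixSummary,
    CancellationSummary,
    CauseLabel,
    ComplianceStats,
    CorrectionPair,
    DEFAULT_EXTREME_FACTOR_THRESHOLD,
    DEFAULT_PAIRING_WINDOW_S,
    TimeConvention,
    classify_cause,
    compute_compliance,
    group_sequences,
    pair_cancellations,
    summarize_alerts,
    summarize_cancellations,
)

SCHEMA_VERSION = 1

ALERT_ROW_LABELS = {
    "hard": "Reprogram limit alert (hard limit)",
    "soft": "Override limit alert (soft limit)",
    "cancelled": "Cancelled infusion",
    "other": "All other alerts",
}

CAUSE_ROW_LABELS = {
    CauseLabel.INCORRECT_MEDICATION: "Incorrect medication selected",
    CauseLabel.WRONG_DOSE: "Wrong dose selected",
    CauseLabel.INDETERMINATE: "Indeterminate cause",
    CauseLabel.WRONG_CHANNEL: "Wrong channel selected",
    CauseLabel.DOSE_CANCELLED_CALC: "Dose cancelled",
    CauseLabel.CONC_LIMIT_BREACH: "Concentration limit breached",
}

POSITION_ROW_LABELS = {
    Position.BEGINNING: "Name beginning (1)",
    Position.MIDDLE: "Name middle (2)",
    Position.END: "Name end (3)",
}


class ReportError(ValueError):
    """Raised when a bundle is missing required sections."""


class PipelineStageError(RuntimeError):
    """A stage failure, carrying the stage name for machine-readable handling."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class ReportBundle:
    """All analysis outputs for one log, plus run metadata."""

    alert_mix: Optional[AlertMixSummary] = None
    causes: Optional[CancellationSummary] = None
    positions: Optional[PositionSummary] = None
    compliance: Optional[ComplianceStats] = None
    char_counts: Optional[CharCountReport] = None
    correction_pairs: list[CorrectionPair] = field(default_factory=list)
    run_meta: dict = field(default_factory=dict)

    def missing_sections(self) -> list[str]:
        required = ("alert_mix", "causes", "positions")
        return [name for name in required if getattr(self, name) is None]


def run_pipeline(
    log: Union[EventLog, str, Path],
    formulary: Union[Formulary, str, Path, None] = None,
    window_s: int = DEFAULT_PAIRING_WINDOW_S,
    convention: TimeConvention = TimeConvention.CANCEL_TO_CORRECT,
    extreme_factor_threshold: float = DEFAULT_EXTREME_FACTOR_THRESHOLD,
) -> ReportBundle:
    """Compose read → validate → group → pair → classify → summarise.

    Deterministic: identical inputs produce identical bundles.  Stage failures
    propagate as :class:`PipelineStageError` naming the stage.  Stage timings
    and record counts land in ``bundle.run_meta``.
    """
    meta: dict = {
        "window_s": window_s,
        "convention": TimeConvention(convention).value,
        "stages": {},
    }

    def stage(name: str, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 — re-raised with stage context
            raise PipelineStageError(name, exc) from exc
        meta["stages"][name] = round(time.perf_counter() - t0, 6)
        return result

    if not isinstance(log, EventLog):
        log = stage("read_event_log", read_event_log, log)
    if formulary is not None and not isinstance(formulary, Formulary):
        formulary = stage("read_formulary", read_formulary, formulary)

    validation = stage("validate_log", validate_log, log)
    meta["n_records"] = len(log)
    meta["n_quarantined"] = len(log.quarantined)
    meta["validation"] = {
        "orphan_resolutions": validation.orphan_resolutions,
        "duplicate_sequence_ids": validation.duplicate_sequence_ids,
        "time_regressions": validation.time_regressions,
    }

    sequences = stage("group_sequences", group_sequences, log)
    meta["n_sequences"] = len(sequences)
    pairs = stage("pair_cancellations", pair_cancellations, sequences, window_s)
    for p in pairs:
        classify_cause(p, formulary=formulary)
    meta["n_cancellations"] = len(pairs)

    alert_mix = stage("summarize_alerts", summarize_alerts, sequences)
    causes = stage(
        "summarize_cancellations",
        summarize_cancellations,
        pairs,
        alert_mix.total,
        TimeConvention(convention),
        extreme_factor_threshold,
    )
    positions = stage("summarize_positions", summarize_positions, pairs)

    compliance: Optional[ComplianceStats]
    try:
        compliance = stage("compute_compliance", compute_compliance, log)
    except PipelineStageError as exc:
        if isinstance(exc.original, ValueError):
            compliance = None  # no starts at all: undefined, reported as absent
        else:
            raise

    char_counts: Optional[CharCountReport] = None
    if formulary is not None and len(formulary):
        char_counts = stage("char_count_distribution", char_count_distribution, formulary)
    else:
        names = sorted(
            {r.medication_name for r in log.records if r.medication_name}
        )
        if names:
            char_counts = stage("char_count_distribution", char_count_distribution, names)

    return ReportBundle(
        alert_mix=alert_mix,
        causes=causes,
        positions=positions,
        compliance=compliance,
        char_counts=char_counts,
        correction_pairs=pairs,
        run_meta=meta,
    )


# --------------------------------------------------------------------------
# rendering


def bundle_to_dict(bundle: ReportBundle) -> dict:
    """Schema-stable JSON form; counts and percentages side by side."""
    missing = bundle.missing_sections()
    if missing:
        raise ReportError(f"bundle is missing sections: {missing}")
    am = bundle.alert_mix
    out: dict = {
        "schema_version": SCHEMA_VERSION,
        "alert_mix": {
            "counts": {
                "hard": am.hard,
                "soft": am.soft,
                "cancelled": am.cancelled,
                "other": am.other,
            },
            "total": am.total,
            "percentages": dict(am.percentages),
        },
        "causes": {
            "counts": {c.value: s.count for c, s in bundle.causes.by_cause.items()},
            "total_cancellations": bundle.causes.total_cancellations,
            "total_alerts": bundle.causes.total_alerts,
            "pct_of_cancellations": {
                c.value: s.pct_of_cancellations for c, s in bundle.causes.by_cause.items()
            },
            "pct_of_alerts": {
                c.value: s.pct_of_alerts for c, s in bundle.causes.by_cause.items()
            },
            "decision_time_stats": {
                c.value: stats for c, stats in bundle.causes.decision_time_stats.items()
            },
            "dose_factor_stats": dict(bundle.causes.dose_factor_stats),
            "extreme_factor_threshold": bundle.causes.extreme_factor_threshold,
        },
        "positions": {
            "counts": {p.value: n for p, n in bundle.positions.counts.items()},
            "total": bundle.positions.total,
            "percentages": {p.value: v for p, v in bundle.positions.percentages.items()},
        },
        "run_meta": bundle.run_meta,
    }
    if bundle.compliance is not None:
        out["compliance"] = {
            "library_starts": bundle.compliance.library_starts,
            "total_starts": bundle.compliance.total_starts,
            "compliance_pct": bundle.compliance.compliance_pct,
        }
    if bundle.char_counts is not None:
        out["char_counts"] = {
            "n": len(bundle.char_counts.counts),
            "mean": bundle.char_counts.mean,
            "sd": bundle.char_counts.sd,
            "histogram": {str(k): v for k, v in bundle.char_counts.histogram.items()},
            "n_at_cap": len(bundle.char_counts.at_cap),
        }
    return out


def _fmt_pct(value: Optional[float]) -> str:
    return "" if value is None else f"{value:.2f}"


def _csv_text(rows: list[list]) -> str:
    import csv

    buf = _io.StringIO()
    csv.writer(buf).writerows(rows)
    return buf.getvalue()


def _render_csv(bundle: ReportBundle) -> dict[str, str]:
    files: dict[str, str] = {}
    am = bundle.alert_mix
    files["alert_mix.csv"] = _csv_text(
        [["category", "label", "count", "pct_of_alerts"]]
        + [
            [key, ALERT_ROW_LABELS[key], getattr(am, key), _fmt_pct(am.percentages[key])]
            for key in ("hard", "soft", "cancelled", "other")
        ]
        + [["total", "All alerts", am.total, _fmt_pct(100.0 if am.total else None)]]
    )
    files["cancellation_causes.csv"] = _csv_text(
        [["cause", "label", "count", "pct_of_cancellations", "pct_of_alerts"]]
        + [
            [
                c.value,
                CAUSE_ROW_LABELS[c],
                s.count,
                _fmt_pct(s.pct_of_cancellations),
                _fmt_pct(s.pct_of_alerts),
            ]
            for c, s in bundle.causes.by_cause.items()
        ]
    )
    files["positions.csv"] = _csv_text(
        [["position", "label", "count", "pct"]]
        + [
            [p.value, POSITION_ROW_LABELS[p], bundle.positions.counts[p], _fmt_pct(bundle.positions.percentages[p])]
            for p in Position
        ]
    )
    pair_rows: list[list] = [
        [
            "seq_id_cancelled",
            "seq_id_replacement",
            "device_id",
            "module_id",
            "cause",
            "latency_s",
            "dose_error_factor",
            "lasa_position",
        ]
    ]
    for p in bundle.correction_pairs:
        pair_rows.append(
            [
                p.cancelled.sequence_id,
                p.replacement.sequence_id if p.replacement else "",
                p.cancelled.device_id,
                p.cancelled.module_id,
                p.cause.value if p.cause else "",
                "" if p.latency_s is None else p.latency_s,
                "" if p.dose_error_factor is None else str(p.dose_error_factor),
                p.lasa_position.value.value if p.lasa_position else "",
            ]
        )
    files["correction_pairs.csv"] = _csv_text(pair_rows)
    if bundle.compliance is not None:
        c = bundle.compliance
        files["compliance.csv"] = _csv_text(
            [
                ["library_starts", "total_starts", "compliance_pct"],
                [c.library_starts, c.total_starts, _fmt_pct(c.compliance_pct)],
            ]
        )
    if bundle.char_counts is not None:
        files["char_counts.csv"] = _csv_text(
            [["char_count", "n_names"]]
            + [[k, v] for k, v in bundle.char_counts.histogram.items()]
        )
    return files


def _render_markdown(bundle: ReportBundle) -> str:
    am = bundle.alert_mix
    lines = ["# DERS log analysis report", ""]
    lines += ["## Alerts by type", "", "| Alert type | n | % |", "|---|---|---|"]
    for key in ("hard", "soft", "cancelled", "other"):
        lines.append(
            f"| {ALERT_ROW_LABELS[key]} | {getattr(am, key):,} | {_fmt_pct(am.percentages[key])} |"
        )
    lines.append(f"| **Total** | {am.total:,} |  |")
    lines += [
        "",
        "## Causes of infusion cancellation",
        "",
        "| Cause | n | % of cancellations | % of alerts |",
        "|---|---|---|---|",
    ]
    for c, s in bundle.causes.by_cause.items():
        of_cancel = _fmt_pct(s.pct_of_cancellations) or "N/A"
        lines.append(
            f"| {CAUSE_ROW_LABELS[c]} | {s.count:,} | {of_cancel} | {_fmt_pct(s.pct_of_alerts)} |"
        )
    lines += [
        "",
        "## Wrong-medication divergence position",
        "",
        "| Word/phrase error position | n | % |",
        "|---|---|---|",
    ]
    for p in Position:
        lines.append(
            f"| {POSITION_ROW_LABELS[p]} | {bundle.positions.counts[p]:,} | {_fmt_pct(bundle.positions.percentages[p])} |"
        )
    if bundle.compliance is not None:
        c = bundle.compliance
        lines += [
            "",
            "## Library compliance",
            "",
            f"{c.compliance_pct:.2f}% ({c.library_starts:,}/{c.total_starts:,}) of "
            "infusions were started through the DERS library.",
        ]
    if bundle.char_counts is not None:
        cc = bundle.char_counts
        sd = f"{cc.sd:.2f}" if cc.sd is not None else "n/a"
        lines += [
            "",
            "## Medication name character counts",
            "",
            f"mean {cc.mean:.2f}, SD {sd}, {len(cc.at_cap)} name(s) at the "
            "20-character field cap.",
        ]
    dt = bundle.causes.decision_time_stats
    if dt:
        lines += [
            "",
            "## Decision times (s)",
            "",
            "| Cause | n | mean | SD | median | min | max |",
            "|---|---|---|---|---|---|---|",
        ]
        for c, s in dt.items():
            sd = f"{s['sd']:.2f}" if s["sd"] is not None else ""
            lines.append(
                f"| {CAUSE_ROW_LABELS[c]} | {s['n']} | {s['mean']:.2f} | {sd} "
                f"| {s['median']:.1f} | {s['min']} | {s['max']} |"
            )
    lines.append("")
    return "\n".join(lines)


def build_report(bundle: ReportBundle, format: str = "markdown"):
    """Render a bundle deterministically.

    ``format='csv'`` returns a mapping of file name → CSV text; ``'markdown'``
    and ``'json'`` return a single document string.  A bundle missing required
    sections raises :class:`ReportError` listing them.
    """
    missing = bundle.missing_sections()
    if missing:
        raise ReportError(f"bundle is missing sections: {missing}")
    if format == "json":
        return json.dumps(bundle_to_dict(bundle), indent=2, sort_keys=True)
    if format == "csv":
        return _render_csv(bundle)
    if format == "markdown":
        return _render_markdown(bundle)
    raise ValueError(f"unknown report format {format!r}")
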