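"""Shared fixtures: record factories and generated logs at two scales."""

from __future__ import annotations

from datetime import datetime

import pytest

from pumpguard import (
    EventLog,
    EventRecord,
    EventType,
    ModuleType,
    default_config,
    default_formulary,
    generate_log,
    run_pipeline,
)


def make_record(
    ts: str,
    event_type: EventType,
    sequence_id: str = "S1",
    device_id: str = "DEV0",
    module_id: str = "DEV0-M0",
    module_type: ModuleType = ModuleType.LARGE_VOLUME,
    name: str = "Heparin",
    dose: float | None = None,
    unit: str = "",
    conc: float | None = None,
) -> EventRecord:
    if event_type in (EventType.BASIC_INFUSION_START, EventType.CALC_START):
        name = ""
    return EventRecord(
        timestamp=datetime.fromisoformat(ts),
        device_id=device_id,
        module_id=module_id,
        module_type=module_type,
        profile="ICU",
        sequence_id=sequence_id,
        event_type=event_type,
        medication_name=name,
        dose_value=dose,
        dose_unit=unit,
        concentration_value=conc,
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def small_run():
    """A compact generated log with ground truth (fast unit-test scale)."""
    cfg = default_config(n_infusion_starts=2_000, seed=7)
    cfg.dose_factor.extreme_outlier_count = 3
    log, truth = generate_log(cfg)
    return cfg, log, truth


@pytest.fixture(scope="session")
def study_run():
    """The study-conditions run: 50,000 infusion starts, fixed seed."""
    cfg = default_config(n_infusion_starts=50_000, seed=1234)
    log, truth = generate_log(cfg)
    bundle = run_pipeline(log, default_formulary())
    return cfg, log, truth, bundle


@pytest.fixture
def empty_log():
    return EventLog([])
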