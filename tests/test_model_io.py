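"""Event-log and formulary I/O: parsing, quarantine, round trips, validation."""

from __future__ import annotations

import io
import random

import pytest

from pumpguard import (
    Dialect,
    EventLog,
    EventRecord,
    EventType,
    MedicationEntry,
    ModuleType,
    default_config,
    generate_log,
    read_event_log,
    read_formulary,
    validate_log,
    write_event_log,
)
from pumpguard.io import DialectError, FormularyError

HEADER = (
    "timestamp,device_id,module_id,module_type,profile,sequence_id,event_type,"
    "medication_name,therapy,dose_value,dose_unit,concentration_value"
)

ROWS = [
    "2019-01-01 10:00:00,D1,D1-M0,LARGE_VOLUME,ICU,S1,PROGRAM_SELECT,Heparin,,500,units/h,",
    "2019-01-01 10:00:05,D1,D1-M0,LARGE_VOLUME,ICU,S1,SOFT_LIMIT_ALERT,Heparin,,500,units/h,",
    "2019-01-01 10:00:20,D1,D1-M0,LARGE_VOLUME,ICU,S1,OVERRIDE,Heparin,,500,units/h,",
]


def test_well_formed_file_parses_every_row():
    log = read_event_log(io.StringIO("\n".join([HEADER, *ROWS])))
    assert len(log) == 3
    assert not log.quarantined
    assert log.records[0].event_type is EventType.PROGRAM_SELECT
    assert log.records[0].dose_value == 500.0


def test_malformed_timestamp_row_is_quarantined_not_dropped():
    bad = "2019-01-01 25:99:00,D1,D1-M0,LARGE_VOLUME,ICU,S2,CANCEL,Heparin,,,,"
    log = read_event_log(io.StringIO("\n".join([HEADER, *ROWS, bad])))
    assert len(log) == 3
    assert len(log.quarantined) == 1
    assert log.quarantined[0].row_index == 3
    # conservation: parsed + quarantined = input data rows
    assert len(log) + len(log.quarantined) == 4


def test_missing_mandatory_column_is_fatal():
    header = HEADER.replace("sequence_id,", "")
    rows = [r.replace(",S1,", ",") for r in ROWS]
    with pytest.raises(DialectError, match="sequence_id"):
        read_event_log(io.StringIO("\n".join([header, *rows])))


def test_dialect_column_map_adapts_foreign_headers():
    foreign = HEADER.replace("timestamp", "event_time")
    dialect = Dialect(column_map={"timestamp": "event_time"})
    log = read_event_log(io.StringIO("\n".join([foreign, *ROWS])), dialect)
    assert len(log) == 3


def test_row_order_does_not_matter():
    shuffled = list(ROWS)
    random.Random(3).shuffle(shuffled)
    a = read_event_log(io.StringIO("\n".join([HEADER, *ROWS])))
    b = read_event_log(io.StringIO("\n".join([HEADER, *shuffled])))
    assert a.records == b.records


def test_generated_log_round_trips_exactly(small_run, tmp_path):
    _cfg, log, _truth = small_run
    path = tmp_path / "log.csv"
    write_event_log(log, path)
    back = read_event_log(path)
    assert len(back) == len(log)
    assert back.records == log.records
    # canonical writes are byte-stable
    path2 = tmp_path / "log2.csv"
    write_event_log(back, path2)
    assert path.read_bytes() == path2.read_bytes()


def test_basic_mode_records_cannot_carry_a_name():
    from datetime import datetime

    with pytest.raises(ValueError, match="medication"):
        EventRecord(
            timestamp=datetime(2019, 1, 1),
            device_id="D1",
            module_id="M0",
            module_type=ModuleType.LARGE_VOLUME,
            profile="ICU",
            sequence_id="S9",
            event_type=EventType.BASIC_INFUSION_START,
            medication_name="Heparin",
        )


# ---- formulary -----------------------------------------------------------

FORM_HEADER = (
    "profile,core_name,therapy_name,tallman_form,soft_min,soft_max,hard_min,"
    "hard_max,conc_min,conc_max,standard_concentrations"
)


def test_formulary_accepts_therapy_entries():
    row = "ONCOLOGY,PACLitaxel,PACLitaxel weekly,PACLitaxel,,,,,,,1.0;0.5"
    form = read_formulary(io.StringIO("\n".join([FORM_HEADER, row])))
    entry = form.get("ONCOLOGY", "PACLitaxel", "PACLitaxel weekly")
    assert entry is not None
    assert entry.standard_concentrations == (1.0, 0.5)


def test_formulary_rejects_oversize_core_name():
    row = f"ICU,{'x' * 21},,,,,,,,,"
    with pytest.raises(FormularyError, match="20 characters"):
        read_formulary(io.StringIO("\n".join([FORM_HEADER, row])))


def test_formulary_rejects_duplicate_keys():
    row = "ICU,Heparin,,,,,,,,,"
    with pytest.raises(FormularyError, match="duplicate"):
        read_formulary(io.StringIO("\n".join([FORM_HEADER, row, row])))


def test_tallman_form_must_match_core_name():
    with pytest.raises(ValueError, match="tallman"):
        MedicationEntry(core_name="Fluconazole", tallman_form="FLUoxetine")


def test_monoclonal_names_fit_the_twenty_char_cap():
    names = [
        "Cantuzumab mertansin",  # truncated at the pump's 20-character field
        "Altumomab pentetate",
        "Talizumab",
        "Trastuzumab",
    ]
    rows = [f"ONCOLOGY,{n},,,,,,,,," for n in names]
    form = read_formulary(io.StringIO("\n".join([FORM_HEADER, *rows])))
    assert len(form) == len(names)
    assert max(len(e.core_name) for e in form) <= 20


# ---- validation ----------------------------------------------------------


def test_clean_log_validates_clean(small_run):
    _cfg, log, _truth = small_run
    report = validate_log(log)
    assert report.clean
    assert report.n_records == len(log)


def test_orphan_cancel_is_counted(record_factory):
    recs = [
        record_factory("2019-01-01 10:00:00", EventType.PROGRAM_SELECT, "S1"),
        record_factory("2019-01-01 10:00:30", EventType.CANCEL, "S1"),
        record_factory("2019-01-01 11:00:00", EventType.CANCEL, "S_ORPHAN"),
    ]
    report = validate_log(EventLog(recs))
    assert report.orphan_resolutions == 1
    assert report.exemplars["orphan_resolutions"] == [2]


def test_time_regressions_match_brute_force_inversion_count(record_factory):
    rng = random.Random(11)
    times = [f"2019-01-01 10:{m:02d}:00" for m in range(30)]
    rng.shuffle(times)
    recs = [
        record_factory(t, EventType.OTHER_ALERT, f"S{i}") for i, t in enumerate(times)
    ]
    expected = sum(
        1
        for i in range(len(recs))
        for j in range(i + 1, len(recs))
        if recs[i].timestamp > recs[j].timestamp
    )
    assert validate_log(EventLog(recs)).time_regressions == expected


def test_duplicate_sequence_ids_across_devices_are_flagged(record_factory):
    recs = [
        record_factory("2019-01-01 10:00:00", EventType.OTHER_ALERT, "SAME", device_id="D1"),
        record_factory("2019-01-01 10:00:00", EventType.OTHER_ALERT, "SAME", device_id="D2", module_id="D2-M0"),
    ]
    assert validate_log(EventLog(recs)).duplicate_sequence_ids == 1
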