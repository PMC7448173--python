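"""Synthetic generator: defaults, determinism, distributions, truth consistency."""

from __future__ import annotations

import io

import numpy as np
import pytest
from scipy import stats

from pumpguard import (
    CauseLabel,
    Position,
    default_config,
    generate_log,
    read_event_log,
    sample_decision_time,
    sample_dose_error_factor,
    write_event_log,
)
from pumpguard.simulate import ConfigError, GeneratorConfig, GroundTruth, LatencyDist


def test_default_config_reflects_study_proportions():
    cfg = default_config()
    assert sum(cfg.alert_mix.values()) == pytest.approx(1.0, abs=1e-12)
    assert cfg.alert_mix["cancel"] == pytest.approx(44_721 / 290_807)
    assert cfg.alert_mix["cancel"] == pytest.approx(0.1537, abs=1e-4)
    assert sum(cfg.cause_mix.values()) == pytest.approx(1.0, abs=1e-12)
    assert cfg.position_targets[Position.BEGINNING] == pytest.approx(0.6979, abs=1e-4)
    assert cfg.compliance_rate == pytest.approx(0.7429, abs=1e-4)
    dist = cfg.decision_time[CauseLabel.INCORRECT_MEDICATION.value]
    assert (dist.mean_s, dist.sd_s, dist.min_s, dist.max_s) == (27.00, 22.25, 4, 113)
    assert cfg.dose_factor.median == 1.5
    assert cfg.dose_factor.extreme_outlier_count == 11


def test_zero_starts_yield_empty_log_and_truth():
    log, truth = generate_log(default_config(n_infusion_starts=0))
    assert len(log) == 0
    assert len(truth) == 0


def test_same_seed_is_byte_identical():
    cfg = default_config(n_infusion_starts=1_000, seed=42)
    cfg.dose_factor.extreme_outlier_count = 2
    outputs = []
    for _ in range(2):
        log, truth = generate_log(cfg)
        buf_log, buf_truth = io.StringIO(), io.StringIO()
        write_event_log(log, buf_log)
        truth.write(buf_truth)
        outputs.append((buf_log.getvalue(), buf_truth.getvalue()))
    assert outputs[0] == outputs[1]


def test_different_seeds_differ():
    from pumpguard.simulate import DoseFactorDist

    def gen(seed):
        cfg = GeneratorConfig(
            n_infusion_starts=200,
            seed=seed,
            dose_factor=DoseFactorDist(extreme_outlier_count=0),
        )
        return generate_log(cfg)[0]

    a, b = gen(1), gen(2)
    assert [r.timestamp for r in a.records] != [r.timestamp for r in b.records]


def test_generated_log_round_trips_through_csv(small_run, tmp_path):
    _cfg, log, _truth = small_run
    path = tmp_path / "sim.csv"
    write_event_log(log, path)
    back = read_event_log(path)
    assert len(back) == len(log)
    assert back.records == log.records


# ---- decision-time distribution -------------------------------------------


def test_decision_time_draws_respect_truncation_and_moments():
    rng = np.random.default_rng(0)
    dist = LatencyDist(27.00, 22.25, 4, 113)
    draws = sample_decision_time(dist, rng, 10_000)
    assert draws.min() >= 4 and draws.max() <= 113
    se = 22.25 / np.sqrt(draws.size)
    assert abs(draws.mean() - 27.00) <= 3 * se


def test_decision_time_distribution_matches_target_by_ks():
    rng = np.random.default_rng(3)
    dist = LatencyDist(27.00, 22.25, 4, 113)
    draws = sample_decision_time(dist, rng, 10_000)
    mu, sigma = dist.lognormal_params()
    lo = stats.norm.cdf((np.log(4) - mu) / sigma)
    hi = stats.norm.cdf((np.log(113) - mu) / sigma)

    def cdf(x):
        z = stats.norm.cdf((np.log(x) - mu) / sigma)
        return (z - lo) / (hi - lo)

    d = stats.kstest(draws, cdf).statistic
    critical_1pct = 1.6276 / np.sqrt(draws.size)
    assert d < critical_1pct


def test_infeasible_truncation_is_a_config_error():
    with pytest.raises(ConfigError):
        LatencyDist(27.0, 22.25, 120, 4).validate()
    with pytest.raises(ConfigError):
        LatencyDist(200.0, 22.25, 4, 113).validate()


# ---- dose factors ----------------------------------------------------------


def test_dose_factor_body_draws_are_positive_and_capped():
    cfg = default_config()
    rng = np.random.default_rng(1)
    draws = sample_dose_error_factor(cfg.dose_factor, rng, 10_000)
    assert (draws > 0).all()
    assert draws.max() <= cfg.dose_factor.body_max
    assert (np.abs(draws - 1.0) >= cfg.dose_factor.unity_gap).all()
    # median near the configured 1.5
    assert np.median(draws) == pytest.approx(1.5, rel=0.05)


def test_exactly_the_requested_extremes_are_planted(small_run):
    cfg, _log, truth = small_run
    threshold = 100.0
    planted = [
        r for r in truth if r.dose_factor is not None and r.dose_factor > threshold
    ]
    assert len(planted) == cfg.dose_factor.extreme_outlier_count


def test_extremes_beyond_wrong_dose_count_is_an_error():
    cfg = default_config(n_infusion_starts=200, seed=0)
    cfg.dose_factor.extreme_outlier_count = 1_000
    with pytest.raises(ConfigError, match="extreme"):
        generate_log(cfg)


# ---- truth consistency -----------------------------------------------------


def test_truth_latencies_and_factors_rederive_from_the_log(small_run):
    _cfg, log, truth = small_run
    by_seq: dict[str, list] = {}
    for r in log.records:
        by_seq.setdefault(r.sequence_id, []).append(r)
    for t in truth:
        if not t.seq_id_replacement:
            continue
        cancelled = by_seq[t.seq_id_cancelled]
        replacement = by_seq[t.seq_id_replacement]
        cancel_t = max(r.timestamp for r in cancelled)
        confirm_t = max(r.timestamp for r in replacement)
        assert int((confirm_t - cancel_t).total_seconds()) == t.latency_s
        if t.dose_factor is not None:
            from pumpguard.units import convert

            dose_c = cancelled[0].dose_value
            dose_r = replacement[0].dose_value
            factor = convert(dose_c, cancelled[0].dose_unit, replacement[0].dose_unit) / dose_r
            assert factor == pytest.approx(t.dose_factor, rel=1e-9)


def test_truth_file_round_trips(small_run, tmp_path):
    _cfg, _log, truth = small_run
    path = tmp_path / "truth.csv"
    truth.write(path)
    back = GroundTruth.read(path)
    assert back.records == truth.records


# ---- config validation and YAML -------------------------------------------


def test_empty_lasa_catalog_with_wrong_medication_share_is_an_error():
    cfg = default_config()
    cfg.lasa_catalog = ()
    with pytest.raises(ConfigError, match="lasa_catalog"):
        cfg.validate()


def test_probability_vectors_must_sum_to_one():
    cfg = default_config()
    cfg.alert_mix["soft"] += 0.01
    with pytest.raises(ConfigError, match="alert_mix"):
        cfg.validate()


def test_config_yaml_round_trip(tmp_path):
    cfg = default_config(n_infusion_starts=500, seed=9)
    path = tmp_path / "config.yaml"
    cfg.to_yaml(path)
    back = GeneratorConfig.from_yaml(path)
    assert back.to_dict() == cfg.to_dict()
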