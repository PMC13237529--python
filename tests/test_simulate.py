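"""Synthetic cohort generator: determinism, calibration, degenerate configs,
round-trips."""
from __future__ import annotations

import statistics
from dataclasses import replace
from datetime import date

import numpy as np
import pytest

from oncotriage.errors import InvalidConfig
from oncotriage.model import Symptom, Tier
from oncotriage.simulate import (
    SimulationConfig,
    calibrate_cutpoints,
    config_from_dict,
    expected_tier_mix,
    simulate_cohort,
    truncated_lognormal_mu,
    write_fixture,
)


@pytest.fixture(scope="module")
def small_bundle():
    return simulate_cohort(replace(SimulationConfig(), n_patients=8, seed=42))


def test_seed_determinism_byte_identical(tmp_path):
    config = replace(SimulationConfig(), n_patients=6, duration_days=30, seed=9)
    paths_a = write_fixture(simulate_cohort(config), tmp_path / "a")
    paths_b = write_fixture(simulate_cohort(config), tmp_path / "b")
    for key in paths_a:
        assert paths_a[key].read_bytes() == paths_b[key].read_bytes(), key


def test_different_seeds_differ(tmp_path):
    a = simulate_cohort(replace(SimulationConfig(), n_patients=6, seed=1))
    b = simulate_cohort(replace(SimulationConfig(), n_patients=6, seed=2))
    assert [c.checkin_id for c in a.checkins] != [c.checkin_id for c in b.checkins] or [
        c.scores for c in a.checkins
    ] != [c.scores for c in b.checkins]


def test_degenerate_single_green_day():
    config = replace(
        SimulationConfig(),
        n_patients=1,
        duration_days=1,
        enrollment_stagger_days=1,
        adherence_p=1.0,
        calibrate_tier_mix=False,
        manual_cutpoints=(100.0, 200.0, 300.0),  # scores can never leave 0
        intraday_event_rate=0.0,
    )
    bundle = simulate_cohort(config)
    assert len(bundle.checkins) == 1
    assert len(bundle.alerts) == 1
    assert bundle.alerts[0].tier is Tier.GREEN
    assert bundle.episodes == []
    assert bundle.encounters == []


def test_zero_adherence_produces_no_checkins():
    config = replace(
        SimulationConfig(), n_patients=3, duration_days=10, adherence_p=0.0
    )
    bundle = simulate_cohort(config)
    assert bundle.checkins == []
    assert sum(w.expected_days for w in bundle.windows) > 0


@pytest.mark.parametrize(
    "overrides",
    [
        {"n_patients": 0},
        {"adherence_p": 1.5},
        {"tier_targets": (0.5, 0.4, 0.2)},
        {"action_mix": (1.0, 1.0, 0.0, 0.0)},
        {"toxicity_spell_autocorr": 1.0},
        {"response_delay_min_minutes": 100.0},
    ],
)
def test_invalid_configs_rejected(overrides):
    with pytest.raises(InvalidConfig):
        replace(SimulationConfig(), **overrides).validate()


def test_unreachable_tier_targets_fail_loudly():
    # with shared patient/day effects this correlated, a red probability of
    # 0.1% cannot coexist with 15% amber: two-amber days force reds
    config = replace(SimulationConfig(), tier_targets=(0.849, 0.15, 0.001))
    with pytest.raises(InvalidConfig):
        calibrate_cutpoints(config)


def test_calibration_hits_targets():
    config = SimulationConfig()
    mix = expected_tier_mix(config, calibrate_cutpoints(config))
    assert mix == pytest.approx(config.tier_targets, abs=1e-6)


def test_truncated_delay_median_is_exact():
    mu = truncated_lognormal_mu(47.0, 0.8, 12.0, 360.0)
    # closed-form check: the truncated CDF at 47 must be exactly one half
    from scipy import stats

    a = stats.norm.cdf((np.log(12.0) - mu) / 0.8)
    b = stats.norm.cdf((np.log(360.0) - mu) / 0.8)
    at_median = stats.norm.cdf((np.log(47.0) - mu) / 0.8)
    assert (at_median - a) / (b - a) == pytest.approx(0.5, abs=1e-10)


def test_enrollment_staggered_within_first_six_weeks(small_bundle):
    config = small_bundle.config
    for w in small_bundle.windows:
        offset = (w.enrolled_from - config.start_date).days
        assert 0 <= offset < config.stagger
        assert w.enrolled_to == config.start_date + timedelta_days(
            config.duration_days - 1
        )


def timedelta_days(d):
    from datetime import timedelta

    return timedelta(days=d)


def test_adherence_recovery_moderate_cohort():
    config = replace(SimulationConfig(), n_patients=200, seed=3)
    bundle = simulate_cohort(config)
    expected = sum(w.expected_days for w in bundle.windows)
    p_hat = len(bundle.checkins) / expected
    se = np.sqrt(config.adherence_p * (1 - config.adherence_p) / expected)
    assert abs(p_hat - config.adherence_p) <= 3 * se


def test_red_burden_right_skew_at_default_config():
    bundle = simulate_cohort(SimulationConfig())
    reds = {p: 0 for p in bundle.patients}
    for a in bundle.alerts:
        if a.tier is Tier.RED:
            reds[a.patient_id] += 1
    values = list(reds.values())
    assert any(v == 0 for v in values)
    assert any(v >= 10 for v in values)
    # right skew: mean exceeds median
    assert np.mean(values) > statistics.median(values)


def test_mid_cycle_toxicity_peak(small_bundle):
    """Amber/red alert rate is higher near the configured peak day of the
    cycle than in the trough."""
    config = replace(small_bundle.config, n_patients=200, seed=17)
    bundle = simulate_cohort(config)
    starts = {w.patient_id: w.enrolled_from for w in bundle.windows}
    peak = trough = peak_n = trough_n = 0
    for checkin, alert in zip(bundle.checkins, bundle.alerts):
        dic = (
            checkin.submitted_at.date() - starts[checkin.patient_id]
        ).days % config.cycle_length_days
        escalating = alert.tier >= Tier.AMBER
        if abs(dic - config.cycle_peak_day) <= 2:
            peak += escalating
            peak_n += 1
        elif min(dic, config.cycle_length_days - dic) <= 2:
            trough += escalating
            trough_n += 1
    assert peak / peak_n > trough / trough_n


def test_responses_only_for_in_hours_reds(small_bundle):
    by_id = {a.alert_id: a for a in small_bundle.alerts}
    responded = {r.alert_id for r in small_bundle.responses}
    in_hours_reds = {
        a.alert_id for a in small_bundle.alerts if a.tier is Tier.RED and a.in_hours
    }
    assert responded == in_hours_reds
    for r in small_bundle.responses:
        assert r.responded_at >= by_id[r.alert_id].raised_at


def test_review_log_covers_every_episode(small_bundle):
    reviewed = {e.episode_id for e in small_bundle.review_log}
    assert reviewed == {e.episode_id for e in small_bundle.episodes}


def test_fixture_roundtrip_losslessness(tmp_path, small_bundle):
    from oncotriage import io as tableio
    from oncotriage.policy import default_policy

    paths = write_fixture(small_bundle, tmp_path)
    policy = default_policy()
    checkins = tableio.read_checkins(paths["checkins"], policy)
    assert len(checkins) == len(small_bundle.checkins)
    assert [c.checkin_id for c in checkins] == [
        c.checkin_id for c in small_bundle.checkins
    ]
    assert [c.scores for c in checkins] == [c.scores for c in small_bundle.checkins]
    assert [c.submitted_at for c in checkins] == [
        c.submitted_at for c in small_bundle.checkins
    ]
    windows = tableio.read_enrollment(paths["enrollment"])
    assert windows == small_bundle.windows
    responses = tableio.read_responses(paths["responses"], policy)
    assert responses == small_bundle.responses
    encounters = tableio.read_encounters(paths["encounters"], policy)
    assert encounters == small_bundle.encounters
    review = tableio.read_review_log(paths["review_log"], policy)
    assert review == small_bundle.review_log


def test_empty_bundle_writes_headers_only(tmp_path):
    config = replace(
        SimulationConfig(), n_patients=1, duration_days=2, adherence_p=0.0
    )
    paths = write_fixture(simulate_cohort(config), tmp_path)
    lines = paths["checkins"].read_text().strip().splitlines()
    assert len(lines) == 1 and lines[0].startswith("checkin_id,")


def test_config_from_dict_roundtrip_and_unknown_keys():
    config = config_from_dict(
        {
            "n_patients": 5,
            "symptom_baseline": {s.value: 0.0 for s in Symptom},
            "actionability_p_by_tier": {"amber": 0.1, "red": 0.9},
            "start_date": "2025-07-11",
        }
    )
    assert config.n_patients == 5
    assert config.start_date == date(2025, 7, 11)
    assert config.actionability_p_by_tier[Tier.RED] == 0.9
    with pytest.raises(InvalidConfig):
        config_from_dict({"nonsense": 1})


def test_pipeline_closure_default_config():
    """simulate -> triage -> episodes -> report chains with no errors."""
    from oncotriage.analytics import cohort_report
    from oncotriage.episodes import attach_outcomes, episode_stats

    bundle = simulate_cohort(replace(SimulationConfig(), seed=5))
    outcomes = attach_outcomes(bundle.episodes, bundle.review_log)
    report = cohort_report(
        bundle.checkins,
        bundle.alerts,
        bundle.windows,
        bundle.responses,
        outcomes,
        episode_stats(bundle.episodes),
    )
    assert report["engagement"]["completed"] == len(
        {(c.patient_id, c.submitted_at.date()) for c in bundle.checkins}
    )
    total = report["alert_distribution"]["total"]
    assert total == len(bundle.checkins)
    assert report["episodes"]["consolidation_factor"] >= 1.0
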