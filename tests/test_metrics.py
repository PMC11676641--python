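"""Tests of the per-track motility metrics and the motile classifier."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from halotrack.core import Track
from halotrack.metrics import (
    MotilityCriteria,
    calibrate_motility_criteria,
    classify_motile,
    compute_track_metrics,
    direction_change_rate,
    estimate_mean_run_duration,
    estimate_mean_speed,
    instantaneous_speeds,
    mean_speed,
    metrics_table,
    speed_dynamic,
    straightness_index,
)
from halotrack.simulate import MotionParams, simulate_brownian, simulate_run_and_tumble

from _oracles import (
    direction_change_rate as o_dcr,
    inst_speeds as o_speeds,
    mean_speed as o_mean_speed,
    random_track,
    speed_dynamic as o_sd,
    straightness as o_straightness,
)


def track(t, x, y, tid="t0"):
    return Track(tid, np.arange(len(t)), np.asarray(t, float), np.asarray(x, float), np.asarray(y, float))


class TestExamples:
    def test_three_four_five_speed(self):
        tr = track([0.0, 1.0], [0.0, 3.0], [0.0, 4.0])
        assert instantaneous_speeds(tr).tolist() == [5.0]
        assert mean_speed(tr) == 5.0

    def test_constant_velocity_speeds(self):
        t = np.arange(10) / 7.0
        tr = track(t, 10.0 * t, np.zeros(10))
        assert np.allclose(instantaneous_speeds(tr), 10.0)
        assert speed_dynamic(tr) == pytest.approx(0.0, abs=1e-9)

    def test_stationary_track_zero_speed(self):
        tr = track([0.0, 1.0, 2.0], [1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        assert mean_speed(tr) == 0.0

    def test_two_value_speed_dynamic(self):
        # speeds 4 and 6 µm/s -> sample SD sqrt(2)
        tr = track([0.0, 1.0, 2.0], [0.0, 4.0, 10.0], [0.0, 0.0, 0.0])
        assert speed_dynamic(tr) == pytest.approx(math.sqrt(2.0), rel=1e-12)

    def test_straight_track_no_direction_changes(self):
        t = np.arange(8) / 7.0
        tr = track(t, 5.0 * t, 5.0 * t)
        assert direction_change_rate(tr) == 0.0
        assert straightness_index(tr) == pytest.approx(1.0)

    def test_single_right_angle_turn_rate(self):
        # one >30-degree event in a 2 s track -> 0.5 events/s
        tr = track([0.0, 1.0, 2.0], [0.0, 5.0, 5.0], [0.0, 0.0, 5.0])
        assert direction_change_rate(tr) == pytest.approx(0.5)

    def test_closed_square_loop_straightness_zero(self):
        tr = track(
            [0.0, 1.0, 2.0, 3.0, 4.0],
            [0.0, 1.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, 1.0, 0.0],
        )
        assert straightness_index(tr) == 0.0

    def test_l_track_straightness(self):
        tr = track([0.0, 1.0, 2.0], [0.0, 3.0, 3.0], [0.0, 0.0, 4.0])
        assert straightness_index(tr) == pytest.approx(5.0 / 7.0, rel=1e-12)

    def test_nonuniform_sampling_mean_speed_is_path_over_duration(self):
        # gap-bridged track: 3 points, unequal dt
        tr = track([0.0, 1.0, 3.0], [0.0, 3.0, 3.0], [0.0, 0.0, 4.0])
        assert mean_speed(tr) == pytest.approx(7.0 / 3.0, rel=1e-12)


class TestErrorsAndMarkers:
    def test_duplicate_timestamps_rejected(self):
        with pytest.raises(ValueError):
            Track("d", [0, 1], [0.0, 0.0], [0.0, 1.0], [0.0, 1.0])

    def test_speed_dynamic_undefined_below_three_points(self):
        tr = track([0.0, 1.0], [0.0, 1.0], [0.0, 0.0])
        assert math.isnan(speed_dynamic(tr))

    def test_zero_path_straightness_is_nan(self):
        tr = track([0.0, 1.0], [2.0, 2.0], [2.0, 2.0])
        assert math.isnan(straightness_index(tr))

    def test_noise_dominated_track_flagged_with_zero_rate(self):
        t = np.arange(5) / 7.0
        tr = track(t, 0.01 * np.array([0, 1, 0, 1, 0]), np.zeros(5))
        assert direction_change_rate(tr) == 0.0
        m = compute_track_metrics(tr)
        assert "noise_dominated" in m.flags


class TestOracleEquivalence:
    def test_metrics_match_bruteforce_on_random_tracks(self, rng):
        for _ in range(200):
            t, x, y = random_track(rng)
            tr = track(t, x, y)
            assert np.allclose(instantaneous_speeds(tr), o_speeds(t, x, y), rtol=1e-9)
            assert mean_speed(tr) == pytest.approx(o_mean_speed(t, x, y), rel=1e-9)
            assert speed_dynamic(tr) == pytest.approx(o_sd(t, x, y), rel=1e-9)
            assert straightness_index(tr) == pytest.approx(o_straightness(x, y), rel=1e-9)
            assert direction_change_rate(tr) == pytest.approx(o_dcr(t, x, y), rel=1e-9)


class TestInvariants:
    @given(st.integers(0, 10_000))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        t, x, y = random_track(rng)
        theta = rng.uniform(0, 2 * np.pi)
        dx, dy = rng.uniform(-50, 50, size=2)
        xr = math.cos(theta) * x - math.sin(theta) * y + dx
        yr = math.sin(theta) * x + math.cos(theta) * y + dy
        a, b = track(t, x, y), track(t, xr, yr)
        assert mean_speed(a) == pytest.approx(mean_speed(b), rel=1e-9)
        assert speed_dynamic(a) == pytest.approx(speed_dynamic(b), rel=1e-9, abs=1e-9)
        assert straightness_index(a) == pytest.approx(straightness_index(b), rel=1e-9)
        assert direction_change_rate(a) == pytest.approx(direction_change_rate(b), rel=1e-9)

    @given(st.integers(0, 10_000))
    def test_net_displacement_never_exceeds_path(self, seed):
        rng = np.random.default_rng(seed)
        t, x, y = random_track(rng)
        m = compute_track_metrics(track(t, x, y))
        assert m.net_displacement_um <= m.path_length_um + 1e-12
        assert 0.0 <= m.straightness_index <= 1.0
        assert m.mean_speed_um_s == pytest.approx(m.path_length_um / m.duration_s, rel=1e-12)


class TestDirectionChangeRateCalibration:
    def test_run_and_tumble_rate_near_tumble_rate(self, motion_params):
        # tau = 1 s, tumbles always >30 degrees -> ~1 event/s at 7 Hz
        rates = []
        for i in range(500):
            tr = simulate_run_and_tumble(motion_params, 60_000 + i)
            rates.append(direction_change_rate(tr))
        assert float(np.mean(rates)) == pytest.approx(1.0, rel=0.15)


class TestClassifier:
    def test_stationary_track_not_motile(self):
        t = np.arange(71) / 7.0
        tr = track(t, np.zeros(71), np.zeros(71))
        assert not classify_motile(tr, MotilityCriteria())

    def test_calibrated_rates(self, motion_params):
        crit = calibrate_motility_criteria(motion_params, seed=7)
        fp = sum(
            classify_motile(simulate_brownian(0.4, motion_params, 70_000 + i), crit)
            for i in range(300)
        )
        p10 = replace(motion_params, mean_speed=10.0, speed_sd=1e-9)
        tp = sum(
            classify_motile(simulate_run_and_tumble(p10, 80_000 + i), crit) for i in range(300)
        )
        assert fp / 300 <= 0.01
        assert tp / 300 >= 0.99

    def test_calibration_tightens_speed_gate(self, motion_params):
        base = MotilityCriteria()
        crit = calibrate_motility_criteria(motion_params, seed=1, base=base)
        assert crit.min_mean_speed_um_s > base.min_mean_speed_um_s
        assert crit.min_net_displacement_um <= base.min_net_displacement_um


class TestMetricsTable:
    def test_empty_input_empty_table(self):
        df = metrics_table([])
        assert len(df) == 0
        assert "mean_speed_um_s" in df.columns

    def test_rows_match_per_op_values(self, motion_params):
        tracks = [simulate_run_and_tumble(motion_params, i) for i in range(3)]
        df = metrics_table(tracks)
        assert len(df) == 3
        for i, tr in enumerate(tracks):
            assert df.loc[i, "mean_speed_um_s"] == pytest.approx(mean_speed(tr), rel=1e-12)
            assert df.loc[i, "straightness_index"] == pytest.approx(
                straightness_index(tr), rel=1e-12
            )

    def test_duplicate_ids_namespaced_by_recording(self):
        t = np.arange(3) / 7.0
        a = Track("t1", np.arange(3), t, t * 5, t * 0, recording_id="rec1")
        b = Track("t1", np.arange(3), t, t * 5, t * 0, recording_id="rec2")
        df = metrics_table([a, b])
        assert df["track_id"].nunique() == 2


class TestParameterRecovery:
    def test_run_duration_estimator_unbiased_free_space(self, motion_params):
        tracks = [simulate_run_and_tumble(motion_params, 90_000 + i) for i in range(150)]
        tau = estimate_mean_run_duration(tracks)
        assert tau == pytest.approx(motion_params.mean_run_duration, rel=0.1)

    def test_speed_estimator_censors_wall_and_tumbles(self, motion_params):
        field = (141.0, 106.0)
        tracks = [
            simulate_run_and_tumble(motion_params, 95_000 + i, field_size=field)
            for i in range(150)
        ]
        v = estimate_mean_speed(tracks, field_size=field)
        assert v == pytest.approx(motion_params.mean_speed, rel=0.05)
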