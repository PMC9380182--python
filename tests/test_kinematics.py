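"""Velocity derivation, onset/offset rules, and per-trial measures."""

import numpy as np
import pytest

from actionselect.kinematics import (
    DetectionConfig,
    Outcome,
    TrialTrajectory,
    VelocityProfile,
    analyze_trial,
    compute_velocity,
    detect_events,
    detect_offset,
    detect_onset,
    measure_trial,
    offset_threshold,
)
from actionselect.synth import minimum_jerk_speed, simulate_trajectory
from actionselect.task_design import Direction

from conftest import make_subject_params, make_trial


def traj_from_x(x, cue_onset=0.0):
    x = np.asarray(x, dtype=float)
    t = cue_onset + np.arange(x.size) / 60.0
    return TrialTrajectory(trial=make_trial(cue_onset=cue_onset), t=t, x=x, y=np.zeros_like(x))


def profile(speed, vx=None):
    speed = np.asarray(speed, dtype=float)
    vx = speed.copy() if vx is None else np.asarray(vx, dtype=float)
    return VelocityProfile(vx=vx, vy=np.zeros_like(speed), speed=np.abs(speed))


class TestComputeVelocity:
    def test_central_difference_value(self):
        # x = [0, 1, 2] deg at 60 Hz -> slope (2-0)/(2/60) = 60 deg/s at the middle
        vel = compute_velocity(traj_from_x([0.0, 1.0, 2.0]))
        assert vel.speed[1] == pytest.approx(60.0)

    def test_constant_position_zero_speed(self):
        vel = compute_velocity(traj_from_x(np.ones(50)))
        assert np.allclose(vel.speed, 0.0)

    def test_minimum_jerk_peak_recovered_within_one_percent(self, noiseless_params):
        params = make_subject_params(movement_duration_s=0.4, amplitude_target_deg=20.0)
        traj, _ = simulate_trajectory(make_trial(), params, seed=1)
        vel = compute_velocity(traj)
        assert vel.speed.max() == pytest.approx(1.875 * 20 / 0.4, rel=0.01)

    def test_resultant_combines_axes(self):
        x = np.arange(10) / 60.0  # 1 deg/s
        traj = TrialTrajectory(
            trial=make_trial(), t=np.arange(10) / 60.0, x=x, y=x
        )
        vel = compute_velocity(traj)
        assert vel.speed[4] == pytest.approx(np.sqrt(2.0))

    def test_short_record_rejected(self):
        with pytest.raises(ValueError):
            TrialTrajectory(
                trial=make_trial(), t=np.array([0.0, 1 / 60]), x=np.zeros(2), y=np.zeros(2)
            )

    def test_irregular_sampling_rejected(self):
        t = np.array([0.0, 1 / 60, 3 / 60, 4 / 60])
        with pytest.raises(ValueError):
            TrialTrajectory(trial=make_trial(), t=t, x=np.zeros(4), y=np.zeros(4))


class TestDetectOnset:
    def test_two_consecutive_suprathreshold_samples(self):
        assert detect_onset(profile([0, 2, 6, 8, 9, 4])) == 2

    def test_alternating_spikes_do_not_trigger(self):
        assert detect_onset(profile([0, 6, 4, 6, 4, 6, 4])) is None

    def test_rest_returns_none(self):
        assert detect_onset(profile(np.zeros(20))) is None

    def test_threshold_is_strict(self):
        assert detect_onset(profile([0, 5.0, 5.0, 0])) is None
        assert detect_onset(profile([0, 5.001, 5.001, 0])) == 1

    def test_search_start_skips_earlier_movement(self):
        speed = [9, 9, 0, 0, 7, 8, 0]
        assert detect_onset(profile(speed), search_start_idx=2) == 4

    def test_fallback_rule_off_by_default_and_documented_variant(self):
        # decaying trace never has two consecutive samples above 5
        speed = [0, 0, 4.0, 3.9, 3.85, 3.84, 3.83, 0]
        assert detect_onset(profile(speed)) is None
        cfg = DetectionConfig(onset_fallback=True)
        idx = detect_onset(profile(speed), config=cfg)
        assert idx is not None and speed[idx] > 0


class TestOffsetThreshold:
    @pytest.mark.parametrize("peak,expected", [(25.0, 10.0), (50.0, 25.0), (150.0, 40.0)])
    def test_printed_mapping(self, peak, expected):
        assert offset_threshold(peak) == expected

    @pytest.mark.parametrize("peak,expected", [(29.999, 10.0), (30.0, 25.0), (100.0, 25.0), (100.001, 40.0)])
    def test_bin_edges_inclusive_middle(self, peak, expected):
        assert offset_threshold(peak) == expected

    def test_negative_peak_rejected(self):
        with pytest.raises(ValueError):
            offset_threshold(-1.0)

    def test_mapping_scales_with_config(self):
        # thresholds expressed in other units keep the same bin logic
        c = np.pi / 180.0
        cfg = DetectionConfig(
            offset_edge_low=30 * c,
            offset_edge_high=100 * c,
            offset_floor_low=10 * c,
            offset_floor_mid=25 * c,
            offset_floor_high=40 * c,
        )
        assert offset_threshold(50 * c, cfg) == pytest.approx(25 * c)


class TestDetectOffset:
    def test_settling_clause(self):
        # post-peak [50, 30, 10, 9.5]: 10 fails (|delta|=20), 9.5 fires (0.5 < 5)
        speed = [0, 6, 50, 30, 10, 9.5]
        assert detect_offset(profile(speed), onset_idx=1, peak_idx=2) == 5

    def test_direction_reversal_clause(self):
        speed = np.array([0, 6, 50, 30, 20.0, 18])
        vx = np.array([0, 6, 50, 30, -20.0, -18])
        assert detect_offset(profile(speed, vx), onset_idx=1, peak_idx=2) == 4

    def test_never_below_floor_returns_none(self):
        speed = [0, 6, 120, 90, 80, 70, 60]
        assert detect_offset(profile(speed), onset_idx=1, peak_idx=2) is None

    def test_onset_after_peak_rejected(self):
        with pytest.raises(ValueError):
            detect_offset(profile([0, 1, 2]), onset_idx=2, peak_idx=1)


class TestEventOrderingAndScale:
    def test_onset_peak_offset_ordered(self, pipeline_detection):
        params = make_subject_params(noise_sd=0.05)
        rng = np.random.default_rng(0)
        for _ in range(25):
            traj, _ = simulate_trajectory(make_trial(), params, rng=rng)
            ev = detect_events(traj, config=pipeline_detection)
            assert ev.onset_idx <= ev.peak_idx <= ev.offset_idx

    def test_unit_rescaling_leaves_indices_unchanged(self):
        # degrees -> radians with all thresholds rescaled: same detected samples
        params = make_subject_params(noise_sd=0.02)
        traj, _ = simulate_trajectory(make_trial(), params, seed=11)
        c = np.pi / 180.0
        scaled = TrialTrajectory(trial=traj.trial, t=traj.t, x=traj.x * c, y=traj.y * c)
        cfg = DetectionConfig()
        cfg_scaled = DetectionConfig(
            onset_threshold=5 * c,
            offset_edge_low=30 * c,
            offset_edge_high=100 * c,
            offset_floor_low=10 * c,
            offset_floor_mid=25 * c,
            offset_floor_high=40 * c,
            offset_delta=5 * c,
        )
        e1 = detect_events(traj, config=cfg)
        e2 = detect_events(scaled, config=cfg_scaled)
        assert (e1.onset_idx, e1.peak_idx, e1.offset_idx) == (
            e2.onset_idx,
            e2.peak_idx,
            e2.offset_idx,
        )


class TestMeasureTrial:
    def test_rt_from_cue_onset(self):
        # onset detected at sample 30 of a trial cued at t=0 -> RT 0.5 s
        x = np.zeros(120)
        x[30:] = np.linspace(0, 15, 90)  # constant 10 deg/s climb
        traj = traj_from_x(x)
        vel = compute_velocity(traj)
        ev = detect_events(traj, vel)
        m = measure_trial(traj, vel, ev)
        assert m.rt == pytest.approx(0.5, abs=1.5 / 60)

    def test_noiseless_rightward_trial_accurate(self, noiseless_params, pipeline_detection):
        traj, _ = simulate_trajectory(make_trial(Direction.RIGHT), noiseless_params, seed=2)
        m = analyze_trial(traj, pipeline_detection)
        assert m.outcome is Outcome.ACCURATE
        assert m.direction_at_peak is Direction.RIGHT
        assert m.movement_time == pytest.approx(0.25, abs=2.5 / 60)
        assert m.amplitude == pytest.approx(15.0, abs=0.5)

    def test_omission_outcome(self, pipeline_detection):
        params = make_subject_params(noise_sd=0.0, omission_prob=1.0)
        traj, _ = simulate_trajectory(make_trial(), params, seed=1)
        m = analyze_trial(traj, pipeline_detection)
        assert m.outcome is Outcome.OMISSION
        assert m.rt is None

    def test_anticipation_outcome(self, pipeline_detection):
        params = make_subject_params(noise_sd=0.0, anticipation_prob=1.0)
        traj, _ = simulate_trajectory(make_trial(), params, seed=6)
        m = analyze_trial(traj, pipeline_detection)
        assert m.outcome is Outcome.ANTICIPATION

    def test_wrong_direction_is_inaccurate(self, pipeline_detection):
        params = make_subject_params(noise_sd=0.0, error_prob=1.0)
        traj, _ = simulate_trajectory(make_trial(Direction.RIGHT), params, seed=3)
        m = analyze_trial(traj, pipeline_detection)
        assert m.outcome is Outcome.INACCURATE
        assert m.direction_at_peak is Direction.LEFT

    def test_path_amplitude_at_least_displacement(self, pipeline_detection):
        params = make_subject_params(noise_sd=0.05)
        traj, _ = simulate_trajectory(make_trial(), params, seed=4)
        disp = analyze_trial(traj, pipeline_detection).amplitude
        cfg = DetectionConfig(smoothing_cutoff_hz=10.0, amplitude_mode="path")
        path = analyze_trial(traj, cfg).amplitude
        assert path >= disp - 1e-9

    def test_noiseless_rt_recovery_within_one_sample(self, noiseless_params, pipeline_detection):
        rng = np.random.default_rng(9)
        hits = 0
        n = 200
        for _ in range(n):
            trial = make_trial(Direction.RIGHT if rng.random() < 0.5 else Direction.LEFT)
            traj, truth = simulate_trajectory(trial, noiseless_params, rng=rng)
            m = analyze_trial(traj, pipeline_detection)
            if abs(m.rt - truth.true_rt) <= 1 / 60 + 1e-9:
                hits += 1
        assert hits / n >= 0.99
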