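"""Synthetic trajectory and cohort generator: profiles, ground truth, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actionselect.synth import (
    CohortConfig,
    TrialKind,
    ground_truth_frame,
    iter_cohort,
    minimum_jerk_position,
    minimum_jerk_speed,
    simulate_cohort,
    simulate_trajectory,
)
from actionselect.task_design import Condition, Direction

from conftest import make_subject_params, make_trial


class TestMinimumJerk:
    def test_profile_endpoints(self):
        assert minimum_jerk_position(0.0, 20.0, 0.4) == pytest.approx(0.0)
        assert minimum_jerk_position(0.4, 20.0, 0.4) == pytest.approx(20.0)
        assert minimum_jerk_position(1.0, 20.0, 0.4) == pytest.approx(20.0)  # clamped

    def test_peak_speed_closed_form(self):
        # peak speed 1.875 D/T at the midpoint
        assert minimum_jerk_speed(0.2, 20.0, 0.4) == pytest.approx(1.875 * 20 / 0.4)
        t = np.linspace(0, 0.4, 10_001)
        assert minimum_jerk_speed(t, 20.0, 0.4).max() == pytest.approx(93.75, rel=1e-6)

    def test_invalid_duration(self):
        with pytest.raises(ValueError):
            minimum_jerk_position(0.1, 20.0, 0.0)

    @settings(deadline=None, derandomize=True)
    @given(
        D=st.floats(1.0, 20.0),
        T=st.floats(0.1, 1.0),
        frac=st.floats(0.0, 1.0),
    )
    def test_monotone_from_zero_to_target(self, D, T, frac):
        t = np.linspace(0, T, 50)
        x = minimum_jerk_position(t, D, T)
        assert np.all(np.diff(x) >= -1e-9)
        assert 0.0 - 1e-9 <= minimum_jerk_position(frac * T, D, T) <= D + 1e-9


class TestSimulateTrajectory:
    def test_noiseless_normal_trial_reaches_target(self, noiseless_params):
        trial = make_trial(Direction.RIGHT)
        traj, truth = simulate_trajectory(trial, noiseless_params, seed=0)
        assert truth.trial_kind is TrialKind.NORMAL
        assert truth.true_direction is Direction.RIGHT
        assert traj.x.max() == pytest.approx(noiseless_params.amplitude_target_deg, abs=1e-6)
        assert np.all(traj.y == 0)

    def test_leftward_trial_is_mirrored(self, noiseless_params):
        trial = make_trial(Direction.LEFT)
        traj, _ = simulate_trajectory(trial, noiseless_params, seed=0)
        assert traj.x.min() == pytest.approx(-noiseless_params.amplitude_target_deg, abs=1e-6)

    def test_sampling_contract(self, noiseless_params):
        trial = make_trial(iti=2.6, cue_onset=10.0)
        traj, _ = simulate_trajectory(trial, noiseless_params, seed=1)
        assert traj.t[0] == pytest.approx(10.0)
        assert len(traj.t) == round((2.0 + 2.6) * 60)
        assert np.allclose(np.diff(traj.t), 1 / 60, atol=1e-9)

    def test_same_seed_identical_samples(self):
        params = make_subject_params(noise_sd=0.05)
        trial = make_trial()
        t1, _ = simulate_trajectory(trial, params, seed=42)
        t2, _ = simulate_trajectory(trial, params, seed=42)
        assert np.array_equal(t1.x, t2.x) and np.array_equal(t1.y, t2.y)

    def test_sampled_peak_speed_matches_closed_form(self):
        # D=20, T=0.4: closed-form peak 93.75 deg/s; the 60-Hz grid may miss
        # the exact midpoint, so compare against the profile on the same grid
        params = make_subject_params(movement_duration_s=0.4, amplitude_target_deg=20.0)
        trial = make_trial()
        traj, truth = simulate_trajectory(trial, params, seed=3)
        rt = truth.true_rt
        grid_speed = minimum_jerk_speed(traj.t - traj.t[0] - rt, 20.0, 0.4)
        finite_diff_peak = np.abs(np.diff(traj.x) * 60).max()
        assert finite_diff_peak <= 93.75 + 1e-6
        assert finite_diff_peak == pytest.approx(grid_speed.max(), rel=0.02)
        assert grid_speed.max() == pytest.approx(93.75, rel=0.01)

    def test_ground_truth_onset_consistent_with_samples(self, noiseless_params):
        # speed must exceed the 5 deg/s onset criterion within 1 sample of truth
        trial = make_trial()
        traj, truth = simulate_trajectory(trial, noiseless_params, seed=8)
        speed = np.abs(np.diff(traj.x)) * 60
        crossing = np.nonzero(speed > 5)[0][0]
        true_idx = round((truth.true_onset - traj.t[0]) * 60)
        assert abs(crossing - true_idx) <= 1

    def test_omission_trial_has_no_movement(self):
        params = make_subject_params(noise_sd=0.0, omission_prob=1.0)
        traj, truth = simulate_trajectory(make_trial(), params, seed=0)
        assert truth.trial_kind is TrialKind.OMISSION
        assert truth.true_onset is None
        assert np.all(traj.x == 0)

    def test_anticipation_rt_below_cutoff(self):
        params = make_subject_params(noise_sd=0.0, anticipation_prob=1.0)
        _, truth = simulate_trajectory(make_trial(), params, seed=0)
        assert truth.trial_kind is TrialKind.ANTICIPATION
        assert truth.true_rt < 0.1

    def test_error_trial_flips_direction(self):
        params = make_subject_params(noise_sd=0.0, error_prob=1.0)
        traj, truth = simulate_trajectory(make_trial(Direction.RIGHT), params, seed=0)
        assert truth.trial_kind is TrialKind.ERROR
        assert truth.true_direction is Direction.LEFT
        assert traj.x.min() < -10

    def test_error_fraction_converges(self):
        # binomial check at n=10,000: observed rate within 4 SE of p=0.1
        p = 0.1
        params = make_subject_params(noise_sd=0.0, error_prob=p)
        rng = np.random.default_rng(17)
        trial = make_trial()
        kinds = [
            simulate_trajectory(trial, params, rng=rng)[1].trial_kind
            for _ in range(10_000)
        ]
        rate = np.mean([k is TrialKind.ERROR for k in kinds])
        se = np.sqrt(p * (1 - p) / 10_000)
        assert abs(rate - p) < 4 * se

    def test_positions_bounded_by_excursion_plus_noise(self):
        params = make_subject_params(noise_sd=0.05, amplitude_target_deg=20.0)
        rng = np.random.default_rng(5)
        for _ in range(50):
            traj, _ = simulate_trajectory(make_trial(), params, rng=rng)
            bound = 20.0 + 4 * 0.05
            assert np.all(np.abs(traj.x) <= bound) and np.all(np.abs(traj.y) <= bound)


class TestCohort:
    def test_scheduled_trial_counts(self):
        cfg = CohortConfig(n_subjects=2, master_seed=0)
        _, trials = simulate_cohort(cfg)
        per_subject = [t for t in trials if t.subject == 1]
        # Day 1: 3 analysis blocks/condition + familiarization; Days 2-4: 4/condition
        analysis = [t for t in per_subject if t.is_analysis]
        select = [t for t in analysis if t.spec.condition is Condition.SELECT]
        assert len(select) == 72 + 96 * 3
        fam = [t for t in per_subject if not t.is_analysis]
        assert len(fam) == 24 and all(t.day == 1 for t in fam)

    def test_degenerate_config_gives_constant_rt_cost(self):
        cfg = CohortConfig(
            n_subjects=3,
            master_seed=1,
            execute_rt_between_sd=0.0,
            rt_cost_between_sd_day1=0.0,
            rt_cost_between_sd_day4=0.0,
            rt_cost_day_residual_sd=0.0,
            rt_cost_mean_day1=0.5,
            rt_cost_mean_day4=0.5,
            day1_blocks_per_condition=1,
            later_blocks_per_condition=1,
        )
        subjects = {}
        for record, _, _ in iter_cohort(cfg):
            subjects[record.subject] = record
        for rec in subjects.values():
            for day in (1, 2, 3, 4):
                assert rec.true_rt_cost_by_day[day] == pytest.approx(0.5)

    def test_master_seed_reproducibility(self, tiny_cohort_config):
        _, t1 = simulate_cohort(tiny_cohort_config)
        _, t2 = simulate_cohort(tiny_cohort_config)
        g1, g2 = ground_truth_frame(t1), ground_truth_frame(t2)
        assert g1.equals(g2)
        assert np.array_equal(t1[0].trajectory.x, t2[0].trajectory.x)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CohortConfig(n_subjects=1)
        with pytest.raises(ValueError):
            CohortConfig(rt_cost_between_sd_day1=-0.1)
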