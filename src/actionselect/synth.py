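"""Synthetic 60-Hz joystick trajectories and whole cohorts with known ground truth.

The generator emulates a spring-centered joystick (maximum excursion 20
degrees of deflection): after a lognormally distributed latent reaction time
the hand drives the stick along x with a minimum-jerk profile toward the
target amplitude, holds briefly, and releases it to the centering spring,
modeled as a critically damped return.  The y axis carries measurement noise
only (the task is purely left/right).  Latent onset and offset times are
realised on the 60-Hz sample grid and recorded as ground truth, so recovery
errors of the downstream detector are well defined in whole samples.

Cohort-level defaults are calibrated to the study conditions the pipeline is
meant to reproduce: Day-1 Execute trials fast (~0.54 s) and accurate (~98%),
Select slower (~1.1 s) and less accurate (~87%), with the Select-Execute
RT cost shrinking from ~0.55 s to ~0.35 s over four practice days while
Execute stays flat.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from actionselect.task_design import (
    Condition,
    Direction,
    TrialSpec,
    counterbalance,
    make_lab_session,
)

SAMPLE_RATE_HZ = 60.0
JOYSTICK_MAX_DEFLECTION_DEG = 20.0

DAYS = (1, 2, 3, 4)


class TrialKind(str, Enum):
    NORMAL = "normal"
    ERROR = "error"
    OMISSION = "omission"
    ANTICIPATION = "anticipation"


def minimum_jerk_position(t, D: float, T: float):
    """Minimum-jerk point-to-point position x(t) = D(10 tau^3 - 15 tau^4 + 6 tau^5).

    ``tau = clamp(t/T, 0, 1)``; the profile starts at 0, ends at ``D`` and has
    peak speed 1.875 D / T at its midpoint.  Accepts scalar or array ``t``.
    """
    if T <= 0:
        raise ValueError("movement duration T must be positive")
    tau = np.clip(np.asarray(t, dtype=float) / T, 0.0, 1.0)
    out = D * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
    return out if out.ndim else float(out)


def minimum_jerk_speed(t, D: float, T: float):
    """Closed-form speed of the minimum-jerk profile (oracle for tests)."""
    if T <= 0:
        raise ValueError("movement duration T must be positive")
    tau = np.clip(np.asarray(t, dtype=float) / T, 0.0, 1.0)
    out = np.abs(D) / T * (30 * tau**2 - 60 * tau**3 + 30 * tau**4)
    return out if out.ndim else float(out)


@dataclass
class SubjectParams:
    """Generative parameters for one subject.

    ``rt_mean_s`` and ``error_prob`` are keyed by (condition, day) and give the
    trial-level mean RT in seconds and direction-error probability.
    """

    rt_mean_s: dict[tuple[Condition, int], float]
    error_prob: dict[tuple[Condition, int], float]
    rt_sigma: float = 0.25  # lognormal shape of trial RT
    movement_duration_s: float = 0.25
    amplitude_target_deg: float = 15.0
    hold_duration_s: float = 0.2
    return_tau_s: float = 0.15  # critically damped spring-return time constant
    omission_prob: float = 0.01
    anticipation_prob: float = 0.0
    position_noise_sd_deg: float = 0.05
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for p in (self.omission_prob, self.anticipation_prob, *self.error_prob.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if not 0.0 < self.amplitude_target_deg <= JOYSTICK_MAX_DEFLECTION_DEG:
            raise ValueError("amplitude_target_deg must be in (0, 20]")
        if any(m <= 0 for m in self.rt_mean_s.values()):
            raise ValueError("trial RT means must be positive")
        if self.movement_duration_s <= 0 or self.return_tau_s <= 0:
            raise ValueError("durations must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Latent per-trial events, on the same absolute time axis as the samples."""

    trial_kind: TrialKind
    true_onset: Optional[float]  # seconds, absolute; None for omissions
    true_offset: Optional[float]
    true_direction: Optional[Direction]


@dataclass(frozen=True)
class TrialTruth(GroundTruth):
    cue_onset: float = 0.0

    @property
    def true_rt(self) -> Optional[float]:
        if self.true_onset is None:
            return None
        return self.true_onset - self.cue_onset


def _draw_rt(mean: float, sigma: float, rng: np.random.Generator) -> float:
    """Lognormal RT parametrised by its mean (mu = ln mean - sigma^2/2)."""
    if sigma == 0.0:
        return mean
    mu = np.log(mean) - 0.5 * sigma**2
    return float(rng.lognormal(mu, sigma))


def simulate_trajectory(
    trial: TrialSpec,
    params: SubjectParams,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    day: int = 1,
):
    """Simulate one trial's 60-Hz samples spanning cue onset to next-trial onset.

    Returns ``(TrialTrajectory, GroundTruth)``.  The latent RT is drawn
    lognormal (uniform [0, 0.1) s on anticipation trials), snapped to the
    sample grid, and drives a signed minimum-jerk excursion along x (sign
    flipped on error trials), a short hold at the target, and a critically
    damped spring return toward center.  Omission trials contain noise only.
    """
    from actionselect.kinematics import TrialTrajectory

    if rng is None:
        rng = np.random.default_rng(seed if seed is not None else params.seed)
    duration = trial.cue_duration + trial.iti
    n = int(round(duration * SAMPLE_RATE_HZ))
    t_local = np.arange(n) / SAMPLE_RATE_HZ
    x = np.zeros(n)

    u = rng.random()
    if u < params.omission_prob:
        kind = TrialKind.OMISSION
    elif u < params.omission_prob + params.anticipation_prob:
        kind = TrialKind.ANTICIPATION
    else:
        kind = TrialKind.NORMAL

    truth: TrialTruth
    if kind is TrialKind.OMISSION:
        rng.random()  # keep draw count aligned across trial kinds
        truth = TrialTruth(
            trial_kind=TrialKind.OMISSION,
            true_onset=None,
            true_offset=None,
            true_direction=None,
            cue_onset=trial.cue_onset,
        )
    else:
        is_error = rng.random() < params.error_prob[(trial.condition, day)]
        direction = (
            trial.prescribed_direction.flipped() if is_error else trial.prescribed_direction
        )
        if kind is TrialKind.ANTICIPATION:
            rt = rng.uniform(0.0, 0.1)
        else:
            rt = _draw_rt(params.rt_mean_s[(trial.condition, day)], params.rt_sigma, rng)
        T = params.movement_duration_s
        # keep the excursion, hold and most of the return inside the window
        rt = min(rt, duration - (T + params.hold_duration_s + 0.3))
        rt = max(rt, 0.0)
        onset_idx = int(round(rt * SAMPLE_RATE_HZ))
        rt = onset_idx / SAMPLE_RATE_HZ  # grid-aligned latent onset
        sign = 1.0 if direction is Direction.RIGHT else -1.0
        A = sign * params.amplitude_target_deg
        move = t_local >= rt
        x[move] = minimum_jerk_position(t_local[move] - rt, A, T)
        release = rt + T + params.hold_duration_s
        ret = t_local >= release
        s = t_local[ret] - release
        x[ret] = A * (1.0 + s / params.return_tau_s) * np.exp(-s / params.return_tau_s)
        if kind is TrialKind.NORMAL and is_error:
            kind = TrialKind.ERROR
        truth = TrialTruth(
            trial_kind=kind,
            true_onset=trial.cue_onset + rt,
            true_offset=trial.cue_onset + rt + T,
            true_direction=direction,
            cue_onset=trial.cue_onset,
        )

    if params.position_noise_sd_deg > 0:
        x = x + rng.normal(0.0, params.position_noise_sd_deg, n)
        y = rng.normal(0.0, params.position_noise_sd_deg, n)
    else:
        y = np.zeros(n)
    traj = TrialTrajectory(trial=trial, t=trial.cue_onset + t_local, x=x, y=y)
    return traj, truth


@dataclass
class CohortConfig:
    """Population-level generative parameters for a synthetic four-day study.

    RT-cost and accuracy population means interpolate linearly between their
    Day-1 and Day-4 values.  Individual RT-cost practice curves follow a
    growth-curve model: a subject baseline offset plus a subject-specific
    linear practice slope (negatively correlated with baseline — high
    starters improve most) plus a small day-level residual.  The three
    curve parameters are derived from the configured Day-1 SD, Day-4 SD and
    Day-1/Day-4 correlation of subject costs, so the simulated cohort
    reproduces those moments while individual curves stay smooth across
    days.  Defaults are calibrated to the study conditions described in the
    module docstring.
    """

    n_subjects: int = 16
    master_seed: int = 0
    execute_rt_mean_day1: float = 0.542
    execute_rt_mean_day4: float = 0.542
    execute_rt_between_sd: float = 0.207
    rt_cost_mean_day1: float = 0.552
    rt_cost_mean_day4: float = 0.353
    rt_cost_between_sd_day1: float = 0.238
    rt_cost_between_sd_day4: float = 0.099
    rt_cost_day1_day4_corr: float = 0.368
    rt_cost_day_residual_sd: float = 0.03
    select_accuracy_day1: float = 0.873
    select_accuracy_day4: float = 0.95
    select_accuracy_between_sd_day1: float = 0.136
    select_accuracy_between_sd_day4: float = 0.05
    execute_accuracy: float = 0.982
    execute_accuracy_between_sd: float = 0.033
    rt_sigma: float = 0.25
    amplitude_mean_deg: float = 15.0
    amplitude_between_sd_deg: float = 2.0
    movement_duration_s: float = 0.25
    position_noise_sd_deg: float = 0.05
    omission_prob: float = 0.01
    anticipation_prob: float = 0.0
    day1_blocks_per_condition: int = 3
    later_blocks_per_condition: int = 4
    trials_per_block: int = 24
    include_familiarization: bool = True

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        for name in (
            "execute_rt_between_sd",
            "rt_cost_between_sd_day1",
            "rt_cost_between_sd_day4",
            "rt_cost_day_residual_sd",
            "select_accuracy_between_sd_day1",
            "select_accuracy_between_sd_day4",
            "execute_accuracy_between_sd",
            "amplitude_between_sd_deg",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1.0 <= self.rt_cost_day1_day4_corr <= 1.0:
            raise ValueError("rt_cost_day1_day4_corr must lie in [-1, 1]")
        self._cost_curve_params()  # fail fast on infeasible moment combinations

    def _cost_curve_params(self) -> tuple[float, float, float, float]:
        """(sigma_b, sigma_s, cov_bs, sigma_e) of the cost growth-curve model.

        b is the subject baseline offset, s the Day-1 -> Day-4 practice-slope
        offset and e the day-level residual:
        cost(d) = mean(d) + b + s*(d-1)/3 + e_d.  Moment matching:
        Var(day1) = sb^2 + se^2; Var(day4) = sb^2 + ss^2 + 2 cbs + se^2;
        Cov(day1, day4) = sb^2 + cbs.
        """
        se = self.rt_cost_day_residual_sd
        v1 = self.rt_cost_between_sd_day1**2
        v4 = self.rt_cost_between_sd_day4**2
        cov14 = (
            self.rt_cost_day1_day4_corr
            * self.rt_cost_between_sd_day1
            * self.rt_cost_between_sd_day4
        )
        vb = v1 - se**2
        if vb < 0:
            raise ValueError("rt_cost_day_residual_sd exceeds the Day-1 between-subject SD")
        cbs = cov14 - vb
        vs = v4 - vb - 2 * cbs - se**2
        if vs < 0:
            raise ValueError("infeasible RT-cost moments: negative practice-slope variance")
        sb, ss = float(np.sqrt(vb)), float(np.sqrt(vs))
        if sb > 0 and ss > 0 and abs(cbs) > sb * ss * (1 + 1e-9):
            raise ValueError("infeasible RT-cost moments: |corr(baseline, slope)| > 1")
        return sb, ss, float(cbs), float(se)


def _interp_day(day: int, day1: float, day4: float) -> float:
    return day1 + (day4 - day1) * (day - 1) / 3.0


def draw_subject_params(
    config: CohortConfig, rng: np.random.Generator
) -> tuple[SubjectParams, dict[int, float]]:
    """Draw one subject's generative parameters from the population model.

    Returns the params plus the subject's latent per-day RT cost (seconds).
    """
    exec_rt = max(0.2, rng.normal(_interp_day(1, config.execute_rt_mean_day1,
                                              config.execute_rt_mean_day4),
                                  config.execute_rt_between_sd))
    sb, ss, cbs, se = config._cost_curve_params()
    cov = np.array([[sb**2, cbs], [cbs, ss**2]])
    baseline, slope = rng.multivariate_normal([0.0, 0.0], cov, method="svd")
    rt_mean: dict[tuple[Condition, int], float] = {}
    error_prob: dict[tuple[Condition, int], float] = {}
    true_cost: dict[int, float] = {}
    exec_acc = float(np.clip(rng.normal(config.execute_accuracy,
                                        config.execute_accuracy_between_sd), 0.5, 1.0))
    sel_acc_dev = rng.normal(0.0, 1.0)
    for day in DAYS:
        cost = (
            _interp_day(day, config.rt_cost_mean_day1, config.rt_cost_mean_day4)
            + baseline
            + slope * (day - 1) / 3.0
            + rng.normal(0.0, se)
        )
        cost = max(0.02, cost)
        true_cost[day] = cost
        e = exec_rt + (_interp_day(day, config.execute_rt_mean_day1, config.execute_rt_mean_day4)
                       - _interp_day(1, config.execute_rt_mean_day1, config.execute_rt_mean_day4))
        rt_mean[(Condition.EXECUTE, day)] = e
        rt_mean[(Condition.SELECT, day)] = e + cost
        sel_acc = float(
            np.clip(
                _interp_day(day, config.select_accuracy_day1, config.select_accuracy_day4)
                + sel_acc_dev
                * _interp_day(day, config.select_accuracy_between_sd_day1,
                              config.select_accuracy_between_sd_day4),
                0.5,
                1.0,
            )
        )
        error_prob[(Condition.SELECT, day)] = 1.0 - sel_acc
        error_prob[(Condition.EXECUTE, day)] = 1.0 - exec_acc
    amplitude = float(np.clip(rng.normal(config.amplitude_mean_deg,
                                         config.amplitude_between_sd_deg),
                              5.0, JOYSTICK_MAX_DEFLECTION_DEG))
    params = SubjectParams(
        rt_mean_s=rt_mean,
        error_prob=error_prob,
        rt_sigma=config.rt_sigma,
        movement_duration_s=config.movement_duration_s,
        amplitude_target_deg=amplitude,
        omission_prob=config.omission_prob,
        anticipation_prob=config.anticipation_prob,
        position_noise_sd_deg=config.position_noise_sd_deg,
    )
    return params, true_cost


@dataclass
class SimulatedTrial:
    subject: int
    day: int
    block: int
    trial: int
    is_analysis: bool
    trajectory: object  # TrialTrajectory
    truth: TrialTruth

    @property
    def spec(self) -> TrialSpec:
        return self.trajectory.trial


@dataclass
class SimulatedSubject:
    subject: int
    first_condition: Condition
    execute_direction: Direction
    params: SubjectParams
    true_rt_cost_by_day: dict[int, float]


def iter_cohort(config: CohortConfig) -> Iterator[tuple[SimulatedSubject, int, list[SimulatedTrial]]]:
    """Yield (subject record, day, that day's simulated trials), lazily.

    Deterministic under ``master_seed``: every subject-day derives its own
    seed stream, so regeneration is bytewise reproducible.
    """
    master = np.random.SeedSequence(config.master_seed)
    subj_seeds = master.spawn(config.n_subjects)
    assignments = counterbalance(config.n_subjects)
    for s_idx in range(config.n_subjects):
        first_cond, exec_dir = assignments[s_idx]
        s_seq = subj_seeds[s_idx]
        param_rng = np.random.default_rng(s_seq.spawn(1)[0])
        params, true_cost = draw_subject_params(config, param_rng)
        record = SimulatedSubject(
            subject=s_idx + 1,
            first_condition=first_cond,
            execute_direction=exec_dir,
            params=params,
            true_rt_cost_by_day=true_cost,
        )
        day_seeds = s_seq.spawn(len(DAYS) + 1)[1:]
        for day, day_seq in zip(DAYS, day_seeds):
            sched_seed, traj_seed = day_seq.spawn(2)
            blocks = (
                config.day1_blocks_per_condition
                if day == 1
                else config.later_blocks_per_condition
            )
            session = make_lab_session(
                day,
                first_cond,
                exec_dir,
                seed=sched_seed,
                blocks_per_condition=blocks,
                trials_per_block=config.trials_per_block,
                include_familiarization=config.include_familiarization,
            )
            # a single rng stream per subject-day keeps trial draws reproducible
            traj_rng = np.random.default_rng(traj_seed)
            trials: list[SimulatedTrial] = []
            for b_idx, block in enumerate(session.blocks):
                for t in block.trials:
                    traj, truth = simulate_trajectory(t, params, rng=traj_rng, day=day)
                    trials.append(
                        SimulatedTrial(
                            subject=record.subject,
                            day=day,
                            block=b_idx,
                            trial=t.trial_index,
                            is_analysis=not block.is_familiarization,
                            trajectory=traj,
                            truth=truth,
                        )
                    )
            yield record, day, trials


def simulate_cohort(config: CohortConfig):
    """Materialise the full synthetic study.

    Returns ``(subjects, trials)``: the per-subject records and the flat list
    of :class:`SimulatedTrial`.  For large cohorts prefer :func:`iter_cohort`.
    """
    subjects: dict[int, SimulatedSubject] = {}
    trials: list[SimulatedTrial] = []
    for record, _day, day_trials in iter_cohort(config):
        subjects[record.subject] = record
        trials.extend(day_trials)
    return list(subjects.values()), trials


def ground_truth_frame(trials: list[SimulatedTrial]) -> pd.DataFrame:
    """Tabulate ground truth keyed by (subject, day, block, trial)."""
    rows = []
    for st in trials:
        tr = st.truth
        rows.append(
            {
                "subject": st.subject,
                "day": st.day,
                "block": st.block,
                "trial": st.trial,
                "is_analysis": st.is_analysis,
                "condition": st.spec.condition.value,
                "trial_kind": tr.trial_kind.value,
                "true_onset": tr.true_onset,
                "true_offset": tr.true_offset,
                "true_rt": tr.true_rt,
                "true_direction": None if tr.true_direction is None else tr.true_direction.value,
            }
        )
    return pd.DataFrame(rows)


def trajectory_frame(trials: list[SimulatedTrial]) -> pd.DataFrame:
    """Long-format samples (subject, day, block, trial, t, x, y)."""
    parts = []
    for st in trials:
        traj = st.trajectory
        parts.append(
            pd.DataFrame(
                {
                    "subject": st.subject,
                    "day": st.day,
                    "block": st.block,
                    "trial": st.trial,
                    "t": traj.t,
                    "x": traj.x,
                    "y": traj.y,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)
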