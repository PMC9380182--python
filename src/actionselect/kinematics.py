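"""Rule-based kinematic event detection and per-trial measures.

Joystick position (x, y, degrees of deflection at 60 Hz) is differentiated
by central finite differences (optionally after zero-phase low-pass
filtering, per standard biomechanics practice) to obtain the resultant
speed.  Movement onset is the first of two consecutive samples whose speed
exceeds 5 deg/s.  Movement offset is the first post-peak sample whose speed
falls below a peak-dependent floor (10 deg/s if the peak was below 30;
25 deg/s for peaks from 30 to 100; 40 deg/s above 100) while the signed x
velocity reverses or the sample-to-sample speed change is under 5 deg/s.

Per-trial measures: RT (cue onset to movement onset), movement time (onset
to offset), amplitude (onset-to-offset displacement, or path length behind a
flag), peak velocity, and direction at the time of peak velocity (sign of x),
which defines direction accuracy against the prescribed direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
from scipy import signal

from actionselect.task_design import Direction, TrialSpec

SAMPLE_RATE_HZ = 60.0
_DT_TOL = 1e-9


@dataclass
class DetectionConfig:
    """Tunable constants of the event-detection rules.

    Thresholds are in deg/s.  ``smoothing_cutoff_hz`` enables a zero-phase
    2nd-order Butterworth low-pass on position before differencing (None
    disables it; the end-to-end pipeline default is 10 Hz).  The onset
    fallback rule (near-zero velocity change after the trace first moves) is
    ambiguous as commonly stated and is off by default.
    """

    onset_threshold: float = 5.0
    onset_fallback: bool = False
    onset_fallback_delta: float = 1.0
    offset_edge_low: float = 30.0
    offset_edge_high: float = 100.0
    offset_floor_low: float = 10.0
    offset_floor_mid: float = 25.0
    offset_floor_high: float = 40.0
    offset_delta: float = 5.0
    smoothing_cutoff_hz: Optional[float] = None
    anticipation_cutoff_s: float = 0.1
    amplitude_mode: str = "displacement"  # or "path"
    include_inaccurate_kinematics: bool = True

    def __post_init__(self) -> None:
        if self.amplitude_mode not in ("displacement", "path"):
            raise ValueError("amplitude_mode must be 'displacement' or 'path'")


@dataclass
class TrialTrajectory:
    """One trial's sampled joystick path on a uniform 60-Hz grid."""

    trial: TrialSpec
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = self.t.size
        if n < 3 or self.x.size != n or self.y.size != n:
            raise ValueError("trajectory arrays must have equal length >= 3")
        dt = np.diff(self.t)
        if np.any(dt <= 0) or np.any(np.abs(dt - 1.0 / SAMPLE_RATE_HZ) > _DT_TOL):
            raise ValueError("t must increase strictly with 1/60 s spacing")

    @property
    def fs(self) -> float:
        return SAMPLE_RATE_HZ

    @property
    def n_samples(self) -> int:
        return self.t.size


@dataclass
class VelocityProfile:
    """Signed per-axis velocities and resultant speed, deg/s per sample."""

    vx: np.ndarray
    vy: np.ndarray
    speed: np.ndarray
    fs: float = SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        if not (len(self.vx) == len(self.vy) == len(self.speed)):
            raise ValueError("velocity arrays must share one length")
        if np.any(np.asarray(self.speed) < 0):
            raise ValueError("speed must be non-negative")


@dataclass
class KinematicEvents:
    onset_idx: Optional[int] = None
    onset_time: Optional[float] = None
    peak_idx: Optional[int] = None
    peak_speed: Optional[float] = None
    offset_idx: Optional[int] = None
    offset_time: Optional[float] = None
    truncated: bool = False  # offset rule never fired; offset set to last sample


class Outcome(str, Enum):
    ACCURATE = "accurate"
    INACCURATE = "inaccurate"
    OMISSION = "omission"
    ANTICIPATION = "anticipation"


@dataclass
class TrialMeasures:
    outcome: Outcome
    rt: Optional[float] = None  # seconds
    movement_time: Optional[float] = None
    amplitude: Optional[float] = None  # degrees
    peak_velocity: Optional[float] = None  # deg/s
    direction_at_peak: Optional[Direction] = None
    truncated: bool = False


from functools import lru_cache


@lru_cache(maxsize=8)
def _design_lowpass(cutoff: float, fs: float):
    sos = signal.butter(2, cutoff, fs=fs, output="sos")
    return sos, signal.sosfilt_zi(sos)


def _zero_phase_lowpass(arr: np.ndarray, cutoff: float, fs: float) -> np.ndarray:
    """Forward-backward 2nd-order Butterworth low-pass, rows filtered at once.

    The record start is extended by even (mirror) reflection — trials begin
    at rest, and an even extension keeps the boundary slope of noise near
    zero instead of propagating it into the filtered trace.  The record end
    (which may sit on the spring-return tail) uses the usual odd extension.
    """
    sos, zi = _design_lowpass(cutoff, fs)
    n = arr.shape[-1]
    padlen = min(n - 1, 30)
    ext = np.concatenate(
        [
            arr[:, padlen:0:-1],
            arr,
            2 * arr[:, -1:] - arr[:, -2 : -padlen - 2 : -1],
        ],
        axis=1,
    )
    z0 = zi[:, None, :] * ext[:, 0][None, :, None]
    fwd, _ = signal.sosfilt(sos, ext, zi=z0)
    rev = fwd[:, ::-1]
    z1 = zi[:, None, :] * rev[:, 0][None, :, None]
    back, _ = signal.sosfilt(sos, rev, zi=z1)
    return back[:, ::-1][:, padlen : padlen + n]


def _central_diff(pos: np.ndarray, fs: float) -> np.ndarray:
    v = np.empty_like(pos)
    v[1:-1] = (pos[2:] - pos[:-2]) * (fs / 2.0)
    v[0] = (pos[1] - pos[0]) * fs
    v[-1] = (pos[-1] - pos[-2]) * fs
    return v


def compute_velocity(
    traj: TrialTrajectory, smoothing_cutoff_hz: Optional[float] = None
) -> VelocityProfile:
    """Differentiate position by central differences (one-sided at the ends).

    With ``smoothing_cutoff_hz`` set, a zero-phase 2nd-order Butterworth
    low-pass is applied to each position axis before differencing.
    """
    if traj.n_samples < 3:
        raise ValueError("need at least 3 samples to differentiate")
    x, y = traj.x, traj.y
    if smoothing_cutoff_hz is not None:
        if not 0 < smoothing_cutoff_hz < traj.fs / 2:
            raise ValueError("smoothing cutoff must lie in (0, Nyquist)")
        x, y = _zero_phase_lowpass(np.vstack([x, y]), float(smoothing_cutoff_hz), traj.fs)
    vx = _central_diff(x, traj.fs)
    vy = _central_diff(y, traj.fs)
    return VelocityProfile(vx=vx, vy=vy, speed=np.hypot(vx, vy), fs=traj.fs)


def detect_onset(
    vel: VelocityProfile,
    search_start_idx: int = 0,
    config: Optional[DetectionConfig] = None,
) -> Optional[int]:
    """First of two consecutive samples with speed strictly above threshold.

    Returns None when no rule fires (omission).  The optional fallback rule
    (velocity change < 1 deg/s for two consecutive samples once the trace has
    left rest) only runs when the primary rule found nothing.
    """
    config = config or DetectionConfig()
    speed = np.asarray(vel.speed)
    n = speed.size
    if not 0 <= search_start_idx < n:
        raise ValueError("search_start_idx out of range")
    above = speed > config.onset_threshold
    pair = above[:-1] & above[1:]
    hits = np.nonzero(pair[search_start_idx:])[0]
    if hits.size:
        return search_start_idx + int(hits[0])
    if config.onset_fallback:
        moving = np.nonzero(speed[search_start_idx:] > 0)[0]
        if moving.size:
            j = search_start_idx + int(moving[0])
            dv = np.abs(np.diff(speed))
            for i in range(j, n - 2):
                if dv[i] < config.onset_fallback_delta and dv[i + 1] < config.onset_fallback_delta:
                    return i
    return None


def offset_threshold(peak_speed: float, config: Optional[DetectionConfig] = None) -> float:
    """Peak-dependent offset floor: 10 below 30, 25 from 30 to 100, 40 above 100."""
    config = config or DetectionConfig()
    if peak_speed < 0:
        raise ValueError("peak speed must be non-negative")
    if peak_speed < config.offset_edge_low:
        return config.offset_floor_low
    if peak_speed <= config.offset_edge_high:
        return config.offset_floor_mid
    return config.offset_floor_high


def detect_offset(
    vel: VelocityProfile,
    onset_idx: int,
    peak_idx: int,
    config: Optional[DetectionConfig] = None,
) -> Optional[int]:
    """Earliest post-peak sample below the offset floor with a direction
    reversal or a speed change under 5 deg/s; None if the rule never fires."""
    config = config or DetectionConfig()
    if onset_idx > peak_idx:
        raise ValueError("onset_idx must not exceed peak_idx")
    speed = np.asarray(vel.speed)
    vx = np.asarray(vel.vx)
    floor = offset_threshold(float(speed[peak_idx]), config)
    lo = peak_idx + 1
    if lo >= speed.size:
        return None
    below = speed[lo:] < floor
    reversal = np.sign(vx[lo:]) != np.sign(vx[lo - 1 : -1])
    settled = np.abs(speed[lo:] - speed[lo - 1 : -1]) < config.offset_delta
    hits = np.nonzero(below & (reversal | settled))[0]
    return lo + int(hits[0]) if hits.size else None


def detect_events(
    traj: TrialTrajectory,
    vel: Optional[VelocityProfile] = None,
    search_start_idx: int = 0,
    config: Optional[DetectionConfig] = None,
) -> KinematicEvents:
    """Run onset -> peak -> offset detection on one trial."""
    config = config or DetectionConfig()
    if vel is None:
        vel = compute_velocity(traj, config.smoothing_cutoff_hz)
    onset = detect_onset(vel, search_start_idx, config)
    if onset is None:
        return KinematicEvents()
    speed = np.asarray(vel.speed)
    peak = onset + int(np.argmax(speed[onset:]))
    offset = detect_offset(vel, onset, peak, config)
    truncated = offset is None
    if offset is None:
        offset = speed.size - 1
    return KinematicEvents(
        onset_idx=onset,
        onset_time=float(traj.t[onset]),
        peak_idx=peak,
        peak_speed=float(speed[peak]),
        offset_idx=offset,
        offset_time=float(traj.t[offset]),
        truncated=truncated,
    )


def measure_trial(
    traj: TrialTrajectory,
    vel: VelocityProfile,
    events: KinematicEvents,
    trial: Optional[TrialSpec] = None,
    config: Optional[DetectionConfig] = None,
) -> TrialMeasures:
    """Derive RT, movement time, amplitude, peak velocity, direction, outcome."""
    config = config or DetectionConfig()
    trial = trial if trial is not None else traj.trial
    if events.onset_idx is None:
        return TrialMeasures(outcome=Outcome.OMISSION)
    if events.offset_idx is None or events.peak_idx is None:
        raise RuntimeError("events incomplete for a detected movement")
    rt = events.onset_time - trial.cue_onset
    movement_time = events.offset_time - events.onset_time
    i, j = events.onset_idx, events.offset_idx
    if config.amplitude_mode == "path":
        dx = np.diff(traj.x[i : j + 1])
        dy = np.diff(traj.y[i : j + 1])
        amplitude = float(np.sum(np.hypot(dx, dy)))
    else:
        amplitude = float(math.hypot(traj.x[j] - traj.x[i], traj.y[j] - traj.y[i]))
    direction = Direction.RIGHT if traj.x[events.peak_idx] > 0 else Direction.LEFT
    if rt < config.anticipation_cutoff_s:
        outcome = Outcome.ANTICIPATION
    elif direction is trial.prescribed_direction:
        outcome = Outcome.ACCURATE
    else:
        outcome = Outcome.INACCURATE
    return TrialMeasures(
        outcome=outcome,
        rt=rt,
        movement_time=movement_time,
        amplitude=amplitude,
        peak_velocity=events.peak_speed,
        direction_at_peak=direction,
        truncated=events.truncated,
    )


def analyze_trial(
    traj: TrialTrajectory, config: Optional[DetectionConfig] = None
) -> TrialMeasures:
    """Convenience: velocity -> events -> measures for one trial."""
    config = config or DetectionConfig()
    vel = compute_velocity(traj, config.smoothing_cutoff_hz)
    start = int(np.searchsorted(traj.t, traj.trial.cue_onset))
    events = detect_events(traj, vel, search_start_idx=start, config=config)
    return measure_trial(traj, vel, events, traj.trial, config)
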