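"""Trial, block, session and fMRI-run schedules for the action selection task.

Two conditions share identical visual cues (a square or circle, small or
large, the large version twice the size of the small).  In Select the cue
dictates direction through an abstract rule; in Execute the participant moves
a fixed, counterbalanced direction on every trial.  Cues last 2 s and are
separated by a 2.0-3.5 s jittered inter-trial interval.  Laboratory blocks
hold 24 trials; Day 1 runs 3 analysis blocks per condition (plus a
familiarization Select block), Days 2-4 run 5 per condition, alternating.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

CUE_DURATION_S = 2.0
ITI_MIN_S = 2.0
ITI_MAX_S = 3.5
LAB_BLOCK_TRIALS = 24
LARGE_TO_SMALL_RATIO = 2.0  # visual size ratio, metadata only

FMRI_TASK_EPOCH_S = 24.0
FMRI_FIXATION_S = 8.0
FMRI_LEADIN_FIXATION_S = 27.0  # instruction / steady-state period before the first task epoch
FMRI_TRIALS_PER_MOVEMENT_EPOCH = 5
FMRI_TOTAL_S = 155.0  # 2 min 35 s


class Shape(str, Enum):
    SQUARE = "square"
    CIRCLE = "circle"


class Size(str, Enum):
    SMALL = "small"
    LARGE = "large"


class Condition(str, Enum):
    SELECT = "Select"
    EXECUTE = "Execute"


class Direction(str, Enum):
    LEFT = "left"
    RIGHT = "right"

    def flipped(self) -> "Direction":
        return Direction.RIGHT if self is Direction.LEFT else Direction.LEFT


@dataclass(frozen=True)
class CueStimulus:
    shape: Shape
    size: Size

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.size.value} {self.shape.value}"


#: The four distinct cue stimuli used by both conditions.
ALL_CUES: tuple[CueStimulus, ...] = tuple(
    CueStimulus(shape, size) for shape, size in itertools.product(Shape, Size)
)


@dataclass(frozen=True)
class RuleMap:
    """Total mapping from cue stimulus to prescribed movement direction."""

    mapping: dict[CueStimulus, Direction]

    def __post_init__(self) -> None:
        if set(self.mapping) != set(ALL_CUES):
            raise ValueError("rule map must assign a direction to all four cue stimuli")
        counts = {d: 0 for d in Direction}
        for d in self.mapping.values():
            counts[d] += 1
        if counts[Direction.LEFT] != 2 or counts[Direction.RIGHT] != 2:
            raise ValueError("each direction must be cued by exactly two stimuli")

    def direction(self, cue: CueStimulus) -> Direction:
        return self.mapping[cue]


def build_rule_map(variant: str = "standard") -> RuleMap:
    """Build the cue->direction rule.

    ``standard``: small square and large circle -> left; large square and
    small circle -> right.  ``mirrored``: both directions flipped.
    """
    standard = {
        CueStimulus(Shape.SQUARE, Size.SMALL): Direction.LEFT,
        CueStimulus(Shape.CIRCLE, Size.LARGE): Direction.LEFT,
        CueStimulus(Shape.SQUARE, Size.LARGE): Direction.RIGHT,
        CueStimulus(Shape.CIRCLE, Size.SMALL): Direction.RIGHT,
    }
    if variant == "standard":
        return RuleMap(standard)
    if variant == "mirrored":
        return RuleMap({cue: d.flipped() for cue, d in standard.items()})
    raise ValueError(f"unknown rule-map variant: {variant!r}")


@dataclass(frozen=True)
class TrialSpec:
    trial_index: int
    condition: Condition
    cue: CueStimulus
    prescribed_direction: Direction
    cue_onset: float  # seconds, block-relative
    iti: float  # seconds, interval following cue offset
    cue_duration: float = CUE_DURATION_S

    def __post_init__(self) -> None:
        if not (ITI_MIN_S <= self.iti <= ITI_MAX_S):
            raise ValueError(f"ITI {self.iti:.3f} s outside [{ITI_MIN_S}, {ITI_MAX_S}]")


@dataclass(frozen=True)
class BlockSpec:
    condition: Condition
    trials: tuple[TrialSpec, ...]
    is_familiarization: bool = False

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def __post_init__(self) -> None:
        if any(t.condition is not self.condition for t in self.trials):
            raise ValueError("all trials in a block must share the block condition")


@dataclass(frozen=True)
class SessionSpec:
    day: int
    first_condition: Condition
    blocks: tuple[BlockSpec, ...]

    @property
    def analysis_blocks(self) -> tuple[BlockSpec, ...]:
        return tuple(b for b in self.blocks if not b.is_familiarization)


class EpochKind(str, Enum):
    FIXATION = "fixation"
    MOVEMENT = "movement"
    REST = "rest"


@dataclass(frozen=True)
class Epoch:
    kind: EpochKind
    duration: float
    trials: tuple[TrialSpec, ...] = ()


@dataclass(frozen=True)
class FmriRunSpec:
    condition: Condition
    epochs: tuple[Epoch, ...]

    @property
    def total_duration(self) -> float:
        return sum(e.duration for e in self.epochs)

    @property
    def movement_trials(self) -> tuple[TrialSpec, ...]:
        return tuple(
            t for e in self.epochs if e.kind is EpochKind.MOVEMENT for t in e.trials
        )


def _balanced_cues(n_trials: int, rng: np.random.Generator) -> list[CueStimulus]:
    """Stratified cue draw: each stimulus appears n//4 or n//4 + 1 times."""
    base, extra = divmod(n_trials, len(ALL_CUES))
    counts = [base] * len(ALL_CUES)
    if extra:
        for i in rng.choice(len(ALL_CUES), size=extra, replace=False):
            counts[i] += 1
    pool = [cue for cue, k in zip(ALL_CUES, counts) for _ in range(k)]
    return [pool[i] for i in rng.permutation(n_trials)]


def _draw_itis(n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.uniform(ITI_MIN_S, ITI_MAX_S, size=n)


def make_block(
    condition: Condition,
    n_trials: int = LAB_BLOCK_TRIALS,
    rule_map: Optional[RuleMap] = None,
    execute_direction: Optional[Direction] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    is_familiarization: bool = False,
) -> BlockSpec:
    """Build one block: balanced random cues, jittered ITIs, cumulated onsets."""
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    condition = Condition(condition)
    if condition is Condition.EXECUTE and execute_direction is None:
        raise ValueError("execute_direction is required for Execute blocks")
    if rule_map is None:
        rule_map = build_rule_map()
    if rng is None:
        rng = np.random.default_rng(seed)
    cues = _balanced_cues(n_trials, rng)
    itis = _draw_itis(n_trials, rng)
    trials = []
    onset = 0.0
    for i, (cue, iti) in enumerate(zip(cues, itis)):
        direction = (
            rule_map.direction(cue)
            if condition is Condition.SELECT
            else Direction(execute_direction)
        )
        trials.append(
            TrialSpec(
                trial_index=i,
                condition=condition,
                cue=cue,
                prescribed_direction=direction,
                cue_onset=onset,
                iti=float(iti),
            )
        )
        onset += CUE_DURATION_S + float(iti)
    return BlockSpec(condition=condition, trials=tuple(trials), is_familiarization=is_familiarization)


def make_lab_session(
    day: int,
    first_condition: Condition,
    execute_direction: Direction,
    rule_map: Optional[RuleMap] = None,
    seed: Optional[int] = None,
    blocks_per_condition: Optional[int] = None,
    trials_per_block: int = LAB_BLOCK_TRIALS,
    include_familiarization: bool = True,
) -> SessionSpec:
    """Build one day's laboratory session of alternating-condition blocks.

    Day 1: a familiarization Select block (flagged, excluded from analysis)
    followed by 3 blocks per condition in alternating order starting with
    ``first_condition`` (72 analysis trials per condition).  Days 2-4: 4
    blocks per condition (96 trials per condition per day).
    ``blocks_per_condition`` overrides the per-day default for scaled-down
    simulation studies.
    """
    if day not in (1, 2, 3, 4):
        raise ValueError(f"day must be in 1..4, got {day}")
    first_condition = Condition(first_condition)
    execute_direction = Direction(execute_direction)
    if rule_map is None:
        rule_map = build_rule_map()
    if blocks_per_condition is None:
        blocks_per_condition = 3 if day == 1 else 4
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    n_blocks = 2 * blocks_per_condition + (1 if day == 1 and include_familiarization else 0)
    child_rngs = [np.random.default_rng(s) for s in ss.spawn(n_blocks)]
    blocks: list[BlockSpec] = []
    rng_iter = iter(child_rngs)
    if day == 1 and include_familiarization:
        blocks.append(
            make_block(
                Condition.SELECT,
                trials_per_block,
                rule_map,
                execute_direction,
                rng=next(rng_iter),
                is_familiarization=True,
            )
        )
    other = (
        Condition.EXECUTE if first_condition is Condition.SELECT else Condition.SELECT
    )
    for _ in range(blocks_per_condition):
        for cond in (first_condition, other):
            blocks.append(
                make_block(cond, trials_per_block, rule_map, execute_direction, rng=next(rng_iter))
            )
    return SessionSpec(day=day, first_condition=first_condition, blocks=tuple(blocks))


def make_fmri_run(
    condition: Condition,
    execute_direction: Optional[Direction] = None,
    rule_map: Optional[RuleMap] = None,
    seed: Optional[int] = None,
) -> FmriRunSpec:
    """Build one block-design imaging run for a single condition.

    Movement (24 s, 5 trials) alternates with rest (24 s); 8-s fixations
    separate the task epochs.  A 27-s lead-in fixation brings the run to the
    paradigm's 2 min 35 s.  Cue duration and ITI jitter match the laboratory
    task; five 2-s cues with four 2.0-3.5 s ITIs always fit a 24-s epoch.
    """
    condition = Condition(condition)
    if condition is Condition.EXECUTE and execute_direction is None:
        raise ValueError("execute_direction is required for Execute runs")
    if rule_map is None:
        rule_map = build_rule_map()
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(2)]
    epochs: list[Epoch] = [Epoch(EpochKind.FIXATION, FMRI_LEADIN_FIXATION_S)]
    for i in range(2):
        block = make_block(
            condition,
            FMRI_TRIALS_PER_MOVEMENT_EPOCH,
            rule_map,
            execute_direction,
            rng=rngs[i],
        )
        epochs.append(Epoch(EpochKind.MOVEMENT, FMRI_TASK_EPOCH_S, block.trials))
        epochs.append(Epoch(EpochKind.FIXATION, FMRI_FIXATION_S))
        epochs.append(Epoch(EpochKind.REST, FMRI_TASK_EPOCH_S))
        epochs.append(Epoch(EpochKind.FIXATION, FMRI_FIXATION_S))
    run = FmriRunSpec(condition=condition, epochs=tuple(epochs))
    assert run.total_duration == FMRI_TOTAL_S
    return run


#: Cycle realising the 2x2 counterbalancing of first condition and Execute
#: direction; both factors stay balanced to within one subject at any n.
_COUNTERBALANCE_CYCLE: tuple[tuple[Condition, Direction], ...] = (
    (Condition.SELECT, Direction.RIGHT),
    (Condition.EXECUTE, Direction.LEFT),
    (Condition.SELECT, Direction.LEFT),
    (Condition.EXECUTE, Direction.RIGHT),
)


def counterbalance(n_subjects: int) -> list[tuple[Condition, Direction]]:
    """Deterministic per-subject (first_condition, execute_direction) assignment."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    cycle = itertools.cycle(_COUNTERBALANCE_CYCLE)
    return [next(cycle) for _ in range(n_subjects)]


def session_to_frame(session: SessionSpec, subject: int | str) -> pd.DataFrame:
    """Serialize a session as one row per trial."""
    rows = []
    for b_idx, block in enumerate(session.blocks):
        for t in block.trials:
            rows.append(
                {
                    "subject": subject,
                    "day": session.day,
                    "block": b_idx,
                    "trial": t.trial_index,
                    "condition": t.condition.value,
                    "shape": t.cue.shape.value,
                    "size": t.cue.size.value,
                    "prescribed_direction": t.prescribed_direction.value,
                    "cue_onset": t.cue_onset,
                    "iti": t.iti,
                    "is_familiarization": block.is_familiarization,
                }
            )
    return pd.DataFrame(rows)
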