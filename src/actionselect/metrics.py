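"""Subject x day x condition aggregates and the RT-cost statistic.

Accuracy is the percentage of directional responses made in the prescribed
direction: omissions and anticipations leave the denominator, since accuracy
is about direction choice.  Mean RT pools accurate trials only.  Movement
time, amplitude and peak velocity pool accurate and inaccurate trials by
default (configurable).  RT cost = Select mean RT - Execute mean RT for one
subject-day, the study's primary action-selection performance measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from actionselect.kinematics import Outcome, TrialMeasures
from actionselect.task_design import Condition


@dataclass(frozen=True)
class ConditionSummary:
    subject: int | str
    day: int
    condition: Condition
    n_trials: int
    n_accurate: int
    n_inaccurate: int
    n_omission: int
    n_anticipation: int
    accuracy_pct: Optional[float]
    mean_rt: Optional[float]
    mean_mt: Optional[float]
    mean_amplitude: Optional[float]
    mean_peak_velocity: Optional[float]


@dataclass(frozen=True)
class RtCostRecord:
    subject: int | str
    day: int
    rt_cost: float


def summarize(
    trials: Sequence[TrialMeasures],
    subject: int | str,
    day: int,
    condition: Condition,
    include_inaccurate_kinematics: bool = True,
) -> ConditionSummary:
    """Aggregate one subject-day-condition cell of trial measures.

    ``trials`` should already exclude familiarization blocks (the pipeline
    filters on the block's analysis flag before calling this).
    """
    trials = list(trials)
    if not trials:
        raise ValueError("cannot summarize an empty trial set")
    n_acc = sum(t.outcome is Outcome.ACCURATE for t in trials)
    n_inacc = sum(t.outcome is Outcome.INACCURATE for t in trials)
    n_omit = sum(t.outcome is Outcome.OMISSION for t in trials)
    n_antic = sum(t.outcome is Outcome.ANTICIPATION for t in trials)
    denom = n_acc + n_inacc
    accuracy = 100.0 * n_acc / denom if denom else None
    rts = [t.rt for t in trials if t.outcome is Outcome.ACCURATE]
    kin_outcomes = (
        (Outcome.ACCURATE, Outcome.INACCURATE)
        if include_inaccurate_kinematics
        else (Outcome.ACCURATE,)
    )
    kin = [t for t in trials if t.outcome in kin_outcomes]
    mean = lambda v: float(np.mean(v)) if v else None  # noqa: E731
    return ConditionSummary(
        subject=subject,
        day=day,
        condition=Condition(condition),
        n_trials=len(trials),
        n_accurate=n_acc,
        n_inaccurate=n_inacc,
        n_omission=n_omit,
        n_anticipation=n_antic,
        accuracy_pct=accuracy,
        mean_rt=mean(rts),
        mean_mt=mean([t.movement_time for t in kin if t.movement_time is not None]),
        mean_amplitude=mean([t.amplitude for t in kin if t.amplitude is not None]),
        mean_peak_velocity=mean(
            [t.peak_velocity for t in kin if t.peak_velocity is not None]
        ),
    )


def rt_cost(select: ConditionSummary, execute: ConditionSummary) -> RtCostRecord:
    """Select mean RT minus Execute mean RT for one subject-day."""
    if select.condition is not Condition.SELECT or execute.condition is not Condition.EXECUTE:
        raise ValueError("arguments must be a (Select, Execute) summary pair")
    if select.subject != execute.subject or select.day != execute.day:
        raise ValueError("summaries must share subject and day")
    if select.mean_rt is None or execute.mean_rt is None:
        raise ValueError("both conditions need at least one accurate trial")
    return RtCostRecord(
        subject=select.subject, day=select.day, rt_cost=select.mean_rt - execute.mean_rt
    )


SUMMARY_COLUMNS = [
    "subject",
    "day",
    "condition",
    "n_trials",
    "accuracy_pct",
    "mean_rt",
    "mean_mt",
    "mean_amplitude",
    "mean_peak_velocity",
    "rt_cost",
]


def build_long_table(
    summaries: Iterable[ConditionSummary],
    rt_costs: Iterable[RtCostRecord] = (),
) -> pd.DataFrame:
    """Tidy table: one row per subject x day x condition, RT cost repeated
    on both condition rows of its subject-day (absent where undefined)."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "subject": s.subject,
                "day": s.day,
                "condition": s.condition.value,
                "n_trials": s.n_trials,
                "accuracy_pct": s.accuracy_pct,
                "mean_rt": s.mean_rt,
                "mean_mt": s.mean_mt,
                "mean_amplitude": s.mean_amplitude,
                "mean_peak_velocity": s.mean_peak_velocity,
            }
        )
    table = pd.DataFrame(rows, columns=SUMMARY_COLUMNS[:-1])
    if table.duplicated(["subject", "day", "condition"]).any():
        dupes = table.loc[
            table.duplicated(["subject", "day", "condition"]), ["subject", "day", "condition"]
        ]
        raise ValueError(f"duplicate summary keys:\n{dupes.to_string(index=False)}")
    cost = pd.DataFrame(
        [{"subject": c.subject, "day": c.day, "rt_cost": c.rt_cost} for c in rt_costs],
        columns=["subject", "day", "rt_cost"],
    )
    if cost.duplicated(["subject", "day"]).any():
        raise ValueError("duplicate RT-cost keys")
    table = table.merge(cost, on=["subject", "day"], how="left")
    return table.sort_values(["subject", "day", "condition"]).reset_index(drop=True)


def rt_cost_table(summaries: Iterable[ConditionSummary]) -> list[RtCostRecord]:
    """Pair Select/Execute summaries per subject-day into RT-cost records.

    Subject-days missing a condition or lacking accurate trials are skipped.
    """
    by_key: dict[tuple, dict[Condition, ConditionSummary]] = {}
    for s in summaries:
        by_key.setdefault((s.subject, s.day), {})[s.condition] = s
    out = []
    for (subject, day), pair in sorted(by_key.items()):
        sel, exe = pair.get(Condition.SELECT), pair.get(Condition.EXECUTE)
        if sel is None or exe is None or sel.mean_rt is None or exe.mean_rt is None:
            continue
        out.append(rt_cost(sel, exe))
    return out
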