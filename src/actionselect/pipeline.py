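"""Configuration and end-to-end runners: simulate -> analyze -> report.

The pipeline default applies a 10-Hz zero-phase low-pass before
differentiation (standard practice for 60-Hz position data; the detector's
5 deg/s onset rule is unreliable on unfiltered differentiated noise).
Every stage is deterministic given the run seed, and file outputs carry a
manifest with the seed, package version and content hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from actionselect import stats as stats_mod
from actionselect.cohort import read_participant_table, split_by_lesion_side, summarize_cohort
from actionselect.kinematics import (
    DetectionConfig,
    Outcome,
    TrialMeasures,
    TrialTrajectory,
    analyze_trial,
)
from actionselect.metrics import ConditionSummary, build_long_table, rt_cost_table, summarize
from actionselect.synth import (
    CohortConfig,
    SimulatedTrial,
    TrialKind,
    ground_truth_frame,
    iter_cohort,
)
from actionselect.task_design import Condition, Direction, TrialSpec, CueStimulus, Shape, Size

log = logging.getLogger("actionselect")

MOVEMENT_VARIABLES = ["accuracy_pct", "mean_rt", "mean_mt", "mean_amplitude", "mean_peak_velocity"]


def default_detection_config() -> DetectionConfig:
    return DetectionConfig(smoothing_cutoff_hz=10.0)


@dataclass
class RunConfig:
    """Declarative configuration of a full synthetic-study run."""

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    detection: DetectionConfig = field(default_factory=default_detection_config)
    gg_correction: bool = False
    t_variant: str = "welch"
    outlier_rule_sd: float = 2.5
    outlier_two_sided: bool = False
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.t_variant not in ("welch", "pooled"):
            raise ValueError(f"unknown t-test variant {self.t_variant!r}")
        if self.outlier_rule_sd <= 0:
            raise ValueError("outlier_rule_sd must be positive")
        self.cohort = dataclasses.replace(self.cohort, master_seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        detection = DetectionConfig(**raw.pop("detection", {}))
        return cls(cohort=cohort, detection=detection, **raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# analysis over simulated (or loaded) trials


def measures_frame(
    trials: Iterable[SimulatedTrial], config: Optional[DetectionConfig] = None
) -> pd.DataFrame:
    """Run event detection + per-trial measurement over trials -> tidy table."""
    config = config or default_detection_config()
    rows = []
    for st in trials:
        m = analyze_trial(st.trajectory, config)
        rows.append(
            {
                "subject": st.subject,
                "day": st.day,
                "block": st.block,
                "trial": st.trial,
                "is_analysis": st.is_analysis,
                "condition": st.spec.condition.value,
                "outcome": m.outcome.value,
                "rt": m.rt,
                "movement_time": m.movement_time,
                "amplitude": m.amplitude,
                "peak_velocity": m.peak_velocity,
                "direction": None if m.direction_at_peak is None else m.direction_at_peak.value,
                "truncated": m.truncated,
            }
        )
    return pd.DataFrame(rows)


def _row_to_measures(row) -> TrialMeasures:
    return TrialMeasures(
        outcome=Outcome(row.outcome),
        rt=None if pd.isna(row.rt) else float(row.rt),
        movement_time=None if pd.isna(row.movement_time) else float(row.movement_time),
        amplitude=None if pd.isna(row.amplitude) else float(row.amplitude),
        peak_velocity=None if pd.isna(row.peak_velocity) else float(row.peak_velocity),
        direction_at_peak=None if row.direction is None else Direction(row.direction),
        truncated=bool(row.truncated),
    )


def summarize_measures(
    measures: pd.DataFrame, include_inaccurate_kinematics: bool = True
) -> tuple[list[ConditionSummary], pd.DataFrame]:
    """Pool analysis-block trials into subject x day x condition summaries
    plus the tidy long table with RT cost."""
    analysis = measures[measures["is_analysis"]]
    summaries = []
    for (subject, day, condition), grp in analysis.groupby(["subject", "day", "condition"]):
        trial_measures = [_row_to_measures(r) for r in grp.itertuples()]
        summaries.append(
            summarize(
                trial_measures,
                subject=subject,
                day=day,
                condition=Condition(condition),
                include_inaccurate_kinematics=include_inaccurate_kinematics,
            )
        )
    costs = rt_cost_table(summaries)
    return summaries, build_long_table(summaries, costs)


def behavioural_stats(long_table: pd.DataFrame, config: Optional[RunConfig] = None) -> dict:
    """The study's statistical battery on the tidy summary table.

    Condition x day within-subject ANOVA on each movement variable, a
    day-only ANOVA on RT cost, Wilcoxon signed-rank Day 1 vs Day 4 on
    direction accuracy per condition, and the outlier sensitivity rule
    applied to Day-1 RT cost.
    """
    config = config or RunConfig()
    out: dict = {"anova": {}, "wilcoxon": {}, "outlier": None}
    for dv in MOVEMENT_VARIABLES:
        out["anova"][dv] = stats_mod.anova_rm(
            long_table, dv, factors=("condition", "day"), gg_correction=config.gg_correction
        )
    cost = long_table.drop_duplicates(["subject", "day"])[["subject", "day", "rt_cost"]]
    out["anova"]["rt_cost"] = stats_mod.anova_rm(cost, "rt_cost", factors=("day",))
    for cond in (Condition.SELECT, Condition.EXECUTE):
        sub = long_table[long_table["condition"] == cond.value].pivot(
            index="subject", columns="day", values="accuracy_pct"
        )
        try:
            out["wilcoxon"][cond.value] = stats_mod.wilcoxon_signed_rank(
                sub[4].to_numpy(), sub[1].to_numpy()
            )
        except stats_mod.DegenerateDataError:
            out["wilcoxon"][cond.value] = None

    day1_cost = cost[cost["day"] == 1].set_index("subject")["rt_cost"].dropna()

    def _day_effect(subjects: Sequence) -> stats_mod.RmAnovaResult:
        kept = cost[cost["subject"].isin(subjects)]
        return stats_mod.anova_rm(kept, "rt_cost", factors=("day",))

    if day1_cost.size >= 3:
        out["outlier"] = stats_mod.outlier_sensitivity(
            day1_cost,
            _day_effect,
            rule_sd=config.outlier_rule_sd,
            two_sided=config.outlier_two_sided,
        )
    return out


def anova_effects_frame(anovas: dict) -> pd.DataFrame:
    parts = []
    for dv, res in anovas.items():
        t = res.table.copy()
        t.insert(0, "dv", dv)
        parts.append(t)
    return pd.concat(parts, ignore_index=True)


def group_report(long_table: pd.DataFrame) -> str:
    """Text report of condition x day group means +- SD for the five
    movement variables, mirroring the study's reporting format."""
    lines = ["Group behavioural performance (mean +- SD across subjects)", ""]
    labels = {
        "accuracy_pct": ("direction accuracy", "%", 1),
        "mean_rt": ("reaction time", "s", 3),
        "mean_mt": ("movement time", "s", 3),
        "mean_amplitude": ("movement amplitude", "deg", 2),
        "mean_peak_velocity": ("peak velocity", "deg/s", 1),
    }
    for dv, (label, unit, nd) in labels.items():
        lines.append(f"{label} ({unit}):")
        for cond in ("Execute", "Select"):
            sub = long_table[long_table["condition"] == cond]
            cells = []
            for day, grp in sub.groupby("day"):
                m, sd = grp[dv].mean(), grp[dv].std(ddof=1)
                cells.append(f"Day {day}: {m:.{nd}f} +- {sd:.{nd}f}")
            lines.append(f"  {cond:8s} " + "; ".join(cells))
        lines.append("")
    cost = long_table.drop_duplicates(["subject", "day"])
    cells = []
    for day, grp in cost.groupby("day"):
        m, sd = grp["rt_cost"].mean(), grp["rt_cost"].std(ddof=1)
        cells.append(f"Day {day}: {m:.3f} +- {sd:.3f}")
    lines.append("RT cost, Select - Execute (s):")
    lines.append("  " + "; ".join(cells))
    return "\n".join(lines) + "\n"


def qc_summary(measures: pd.DataFrame) -> pd.DataFrame:
    """Stage-level QC: omissions, anticipations and truncated offsets."""
    grp = measures.groupby(["subject", "day"])
    return pd.DataFrame(
        {
            "n_trials": grp.size(),
            "n_omission": grp.apply(lambda g: int((g["outcome"] == "omission").sum()), include_groups=False),
            "n_anticipation": grp.apply(
                lambda g: int((g["outcome"] == "anticipation").sum()), include_groups=False
            ),
            "n_truncated": grp.apply(lambda g: int(g["truncated"].sum()), include_groups=False),
        }
    ).reset_index()


# ---------------------------------------------------------------------------
# file IO


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(out_dir: Path, seed: int, files: Sequence[Path]) -> Path:
    from actionselect import __version__

    lines = [f"seed: {seed}", f"package_version: {__version__}", "files:"]
    for f in sorted(files):
        lines.append(f"  {f.name}: {_sha256(f)}")
    manifest = out_dir / "manifest.txt"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest


def run_simulate(config: RunConfig, out_dir: str | Path) -> list[Path]:
    """Generate the synthetic cohort and write trajectory + ground-truth files.

    One long-format trajectory file per subject-day plus a trial-metadata
    table and a ground-truth table; a manifest records seed, version and
    content hashes.  Reruns with the same seed are bytewise identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    meta_rows = []
    gt_frames = []
    for record, day, trials in iter_cohort(config.cohort):
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
                        "t": np.round(traj.t, 9),
                        "x": np.round(traj.x, 6),
                        "y": np.round(traj.y, 6),
                    }
                )
            )
            spec = st.spec
            meta_rows.append(
                {
                    "subject": st.subject,
                    "day": st.day,
                    "block": st.block,
                    "trial": st.trial,
                    "is_analysis": st.is_analysis,
                    "condition": spec.condition.value,
                    "shape": spec.cue.shape.value,
                    "size": spec.cue.size.value,
                    "prescribed_direction": spec.prescribed_direction.value,
                    "cue_onset": spec.cue_onset,
                    "iti": spec.iti,
                }
            )
        path = out / f"trajectories_s{record.subject:02d}_d{day}.csv"
        pd.concat(parts, ignore_index=True).to_csv(path, index=False)
        written.append(path)
        gt_frames.append(ground_truth_frame(trials))
        log.info("simulated subject %d day %d (%d trials)", record.subject, day, len(trials))
    meta = pd.DataFrame(meta_rows)
    meta_path = out / "trials.csv"
    meta.to_csv(meta_path, index=False)
    gt_path = out / "ground_truth.csv"
    pd.concat(gt_frames, ignore_index=True).to_csv(gt_path, index=False)
    written += [meta_path, gt_path]
    write_manifest(out, config.seed, written)
    return written


def load_simulation(in_dir: str | Path) -> list[SimulatedTrial]:
    """Reload a simulated dataset written by :func:`run_simulate`."""
    in_dir = Path(in_dir)
    meta_path = in_dir / "trials.csv"
    if not meta_path.exists():
        raise FileNotFoundError(f"no trial table at {meta_path}")
    meta = pd.read_csv(meta_path)
    key = ["subject", "day", "block", "trial"]
    meta = meta.set_index(key)
    gt_path = in_dir / "ground_truth.csv"
    gt = pd.read_csv(gt_path).set_index(key) if gt_path.exists() else None
    trials: list[SimulatedTrial] = []
    for path in sorted(in_dir.glob("trajectories_*.csv")):
        frame = pd.read_csv(path)
        for k, grp in frame.groupby(key, sort=True):
            try:
                m = meta.loc[k]
            except KeyError as exc:
                raise ValueError(f"{path}: trial {k} missing from trials.csv") from exc
            spec = TrialSpec(
                trial_index=int(k[3]),
                condition=Condition(m["condition"]),
                cue=CueStimulus(Shape(m["shape"]), Size(m["size"])),
                prescribed_direction=Direction(m["prescribed_direction"]),
                cue_onset=float(m["cue_onset"]),
                iti=float(m["iti"]),
            )
            traj = TrialTrajectory(
                trial=spec,
                t=grp["t"].to_numpy(),
                x=grp["x"].to_numpy(),
                y=grp["y"].to_numpy(),
            )
            truth = None
            if gt is not None:
                g = gt.loc[k]
                from actionselect.synth import TrialTruth

                truth = TrialTruth(
                    trial_kind=TrialKind(g["trial_kind"]),
                    true_onset=None if pd.isna(g["true_onset"]) else float(g["true_onset"]),
                    true_offset=None if pd.isna(g["true_offset"]) else float(g["true_offset"]),
                    true_direction=None
                    if pd.isna(g["true_direction"])
                    else Direction(g["true_direction"]),
                    cue_onset=float(m["cue_onset"]),
                )
            trials.append(
                SimulatedTrial(
                    subject=int(k[0]),
                    day=int(k[1]),
                    block=int(k[2]),
                    trial=int(k[3]),
                    is_analysis=bool(m["is_analysis"]),
                    trajectory=traj,
                    truth=truth,
                )
            )
    return trials


def run_analyze(
    trials: Iterable[SimulatedTrial] | str | Path,
    config: Optional[RunConfig] = None,
    out_dir: Optional[str | Path] = None,
) -> dict:
    """kinematics -> metrics -> stats over simulated or loaded trials."""
    config = config or RunConfig()
    if isinstance(trials, (str, Path)):
        trials = load_simulation(trials)
    measures = measures_frame(trials, config.detection)
    summaries, long_table = summarize_measures(measures)
    stats = behavioural_stats(long_table, config)
    report = group_report(long_table)
    result = {
        "measures": measures,
        "long_table": long_table,
        "stats": stats,
        "report": report,
        "qc": qc_summary(measures),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        files = []
        for name, frame in (
            ("trial_measures.csv", measures),
            ("condition_summaries.csv", long_table),
            ("anova_effects.csv", anova_effects_frame(stats["anova"])),
            ("qc_summary.csv", result["qc"]),
        ):
            p = out / name
            frame.to_csv(p, index=False)
            files.append(p)
        rp = out / "report.txt"
        rp.write_text(report)
        files.append(rp)
        write_manifest(out, config.seed, files)
    return result


def ground_truth_comparison(
    trials: Sequence[SimulatedTrial], config: Optional[DetectionConfig] = None
) -> pd.DataFrame:
    """Per-trial detection errors against ground truth (validation harness)."""
    config = config or default_detection_config()
    rows = []
    for st in trials:
        if st.truth is None:
            raise ValueError("trials carry no ground truth")
        m = analyze_trial(st.trajectory, config)
        tr = st.truth
        detected = m.outcome not in (Outcome.OMISSION,)
        row = {
            "subject": st.subject,
            "day": st.day,
            "block": st.block,
            "trial": st.trial,
            "trial_kind": tr.trial_kind.value,
            "detected": detected,
            "outcome": m.outcome.value,
        }
        if detected and tr.true_onset is not None:
            onset_time = st.trajectory.trial.cue_onset + m.rt
            row["onset_error_s"] = onset_time - tr.true_onset
            offset_time = onset_time + m.movement_time
            row["offset_error_s"] = offset_time - tr.true_offset
            row["direction_correct"] = (
                m.direction_at_peak is not None and m.direction_at_peak is tr.true_direction
            )
        rows.append(row)
    return pd.DataFrame(rows)


def run_cohort_analysis(
    table_path: Optional[str | Path] = None,
    metrics: Optional[pd.DataFrame] = None,
    t_variant: str = "welch",
) -> dict:
    """Cohort summary (printed-table style means) and optional LBD/RBD
    subgroup comparisons of behavioural metrics."""
    records = read_participant_table(table_path)
    mean_row = {
        col: summarize_cohort(records, col, dec)
        for col, dec in (
            ("age", 1),
            ("months_post_stroke", 1),
            ("lesion_volume_cc", 1),
            ("cst_fa_ratio", 2),
            ("tulia", 1),
            ("ue_fm", 1),
            ("bbt_more", 1),
            ("bbt_less", 1),
            ("sis_hand", 1),
        )
    }
    out = {"records": records, "mean_row": mean_row, "subgroups": None}
    lbd, rbd = split_by_lesion_side(records, metrics)
    out["sizes"] = (len(lbd), len(rbd))
    if metrics is not None:
        tests = {}
        for col in metrics.columns:
            if col == "subject":
                continue
            try:
                tests[col] = stats_mod.two_sample_t(
                    lbd[col].dropna(), rbd[col].dropna(), variant=t_variant
                )
            except (ValueError, stats_mod.DegenerateDataError):
                tests[col] = None
        out["subgroups"] = tests
    return out
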