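"""Build the counterbalanced four-day practice schedules for a 16-person cohort.

Writes the full per-trial schedule to scratch/schedules/ and a compact
per-day trial-count audit to results/schedule_counts.csv.  Expected counts:
72 analysis trials per condition on Day 1 (plus a 24-trial familiarization
Select block) and 96 per condition on Days 2-4, with the first condition and
the Execute direction counterbalanced across subjects.
"""

from pathlib import Path

import pandas as pd

from actionselect.task_design import counterbalance, make_lab_session, session_to_frame

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "schedules"
RESULTS = ROOT / "results"


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    frames = []
    for subject, (first, exec_dir) in enumerate(counterbalance(16), start=1):
        for day in (1, 2, 3, 4):
            session = make_lab_session(day, first, exec_dir, seed=1000 * subject + day)
            frame = session_to_frame(session, subject)
            frame["first_condition"] = first.value
            frame["execute_direction"] = exec_dir.value
            frames.append(frame)
    schedule = pd.concat(frames, ignore_index=True)
    schedule.to_csv(SCRATCH / "full_schedule.csv", index=False)

    counts = (
        schedule[~schedule["is_familiarization"]]
        .groupby(["day", "condition"])
        .agg(n_trials=("trial", "size"), n_subjects=("subject", "nunique"))
        .reset_index()
    )
    counts["trials_per_subject"] = counts["n_trials"] // counts["n_subjects"]
    counts.to_csv(RESULTS / "schedule_counts.csv", index=False)
    print(counts.to_string(index=False))
    firsts = schedule.drop_duplicates("subject")["first_condition"].value_counts()
    print(f"\nfirst-condition counterbalance: {firsts.to_dict()}")
    print(f"full schedule ({len(schedule)} trials) -> {SCRATCH / 'full_schedule.csv'}")


if __name__ == "__main__":
    main()
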