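"""Simulate the default synthetic cohort: 16 subjects, four practice days.

Joystick trajectories (60 Hz) with latent ground truth are written to
scratch/cohort/ (bulky), and a small ground-truth audit — trial-kind counts
and latent RT-cost means per day — to results/ground_truth_summary.csv.
"""

from pathlib import Path

import pandas as pd

from actionselect.pipeline import RunConfig, run_simulate

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"
SEED = 1


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig(seed=SEED)
    files = run_simulate(cfg, SCRATCH)
    print(f"wrote {len(files)} files to {SCRATCH} (seed {SEED})")

    gt = pd.read_csv(SCRATCH / "ground_truth.csv")
    kinds = gt.groupby(["condition", "trial_kind"]).size().unstack(fill_value=0)
    ok = gt[gt["is_analysis"] & (gt["trial_kind"] == "normal")]
    rt = ok.groupby(["condition", "day"])["true_rt"].mean().unstack("condition")
    rt["true_rt_cost"] = rt["Select"] - rt["Execute"]
    summary = rt.round(4).reset_index()
    summary.to_csv(RESULTS / "ground_truth_summary.csv", index=False)
    print("\ntrial kinds per condition:\n", kinds.to_string())
    print("\nlatent mean RT and RT cost by day:\n", summary.to_string(index=False))


if __name__ == "__main__":
    main()
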