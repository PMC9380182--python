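"""Run event detection and behavioural aggregation over the simulated cohort.

Reads scratch/cohort/ (run 02_simulate_cohort.py first), detects movement
onset/offset/peak on every trial, derives RT, movement time, amplitude, peak
velocity and direction accuracy, and pools them into subject x day x
condition summaries with RT cost.  Per-trial measures go to scratch/
(thousands of rows); the condition summaries, QC counts and the group
means +- SD report go to results/.
"""

from pathlib import Path

from actionselect.pipeline import RunConfig, run_analyze

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
SEED = 1


def main() -> None:
    sim_dir = SCRATCH / "cohort"
    if not (sim_dir / "trials.csv").exists():
        raise SystemExit(f"no simulated cohort at {sim_dir}; run 02_simulate_cohort.py first")
    cfg = RunConfig(seed=SEED)
    result = run_analyze(sim_dir, cfg, SCRATCH / "analysis")
    result["long_table"].to_csv(RESULTS / "condition_summaries.csv", index=False)
    result["qc"].to_csv(RESULTS / "qc_summary.csv", index=False)
    (RESULTS / "report.txt").write_text(result["report"])
    print(result["report"])
    qc = result["qc"]
    print(
        f"QC: {qc['n_omission'].sum()} omissions, {qc['n_anticipation'].sum()} "
        f"anticipations, {qc['n_truncated'].sum()} truncated offsets "
        f"across {qc['n_trials'].sum()} trials"
    )


if __name__ == "__main__":
    main()
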