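"""Validate the event detector against the generator's latent ground truth.

Two checks: (a) per-trial onset/offset error quantiles and direction
recovery over the simulated cohort of 02_simulate_cohort.py; (b) a
standalone 1,000-trial recovery study at the default 0.05-degree position
noise.  Writes results/validation.csv.
"""

from pathlib import Path

import pandas as pd

from actionselect.pipeline import ground_truth_comparison, load_simulation
from actionselect.validation import detection_recovery

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SEED = 1


def main() -> None:
    rows = []
    rec = detection_recovery(n_trials=1000, noise_sd=0.05, seed=SEED)
    for key, value in rec.items():
        if key != "n":
            rows.append({"study": "recovery_1000_trials", "metric": key, "value": value})
    print("single-trial recovery:", {k: round(v, 3) for k, v in rec.items()})

    sim_dir = ROOT / "scratch" / "cohort"
    if (sim_dir / "trials.csv").exists():
        trials = load_simulation(sim_dir)
        cmp = ground_truth_comparison(trials)
        moved = cmp.dropna(subset=["onset_error_s"])
        for col in ("onset_error_s", "offset_error_s"):
            q = moved[col].abs().quantile([0.5, 0.9, 0.99]) * 1000
            for p, v in q.items():
                rows.append({"study": "cohort", "metric": f"{col}_abs_p{int(p * 100)}_ms",
                             "value": v})
        rows.append({"study": "cohort", "metric": "direction_correct_pct",
                     "value": 100 * moved["direction_correct"].mean()})
        print(f"cohort: {len(moved)} movement trials, "
              f"median |onset error| {moved['onset_error_s'].abs().median() * 1000:.1f} ms")
    else:
        print(f"(no cohort at {sim_dir}; run 02_simulate_cohort.py for the cohort check)")
    frame = pd.DataFrame(rows)
    RESULTS.mkdir(parents=True, exist_ok=True)
    frame.to_csv(RESULTS / "validation.csv", index=False)
    print(frame.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
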