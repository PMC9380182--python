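"""Plot practice curves: RT by condition, RT cost, and accuracy across days.

Thin lines are individual subjects, squares the group mean — the standard
presentation for four-day practice data.  PNGs go to scratch/figures/.
Requires results/condition_summaries.csv.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
FIGS = ROOT / "scratch" / "figures"


def spaghetti(ax, table, value, title, ylabel):
    for _, grp in table.groupby("subject"):
        ax.plot(grp["day"], grp[value], color="0.75", lw=0.8)
    mean = table.groupby("day")[value].mean()
    ax.plot(mean.index, mean.values, "s-", color="k", ms=6)
    ax.set(title=title, xlabel="practice day", ylabel=ylabel, xticks=[1, 2, 3, 4])


def main() -> None:
    path = RESULTS / "condition_summaries.csv"
    if not path.exists():
        raise SystemExit(f"{path} missing; run 03_detect_and_summarize.py first")
    table = pd.read_csv(path)
    FIGS.mkdir(parents=True, exist_ok=True)

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.6), constrained_layout=True)
    spaghetti(axes[0], table.query("condition == 'Select'"), "mean_rt",
              "Select reaction time", "RT (s)")
    cost = table.drop_duplicates(["subject", "day"])
    spaghetti(axes[1], cost, "rt_cost", "RT cost (Select - Execute)", "RT cost (s)")
    spaghetti(axes[2], table.query("condition == 'Select'"), "accuracy_pct",
              "Select direction accuracy", "accuracy (%)")
    out = FIGS / "practice_curves.png"
    fig.savefig(out, dpi=150)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
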