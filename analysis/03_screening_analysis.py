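"""Screening statistics on the extracted intensities.

Joins the intensity table with the subject table and runs the full analysis:
Pearson correlation of each channel with TsB, discrimination-limit screening
(green limit 212, blue limit 190, clinical threshold TsB > 205 μmol/L), an
exhaustive threshold scan, the 3-SD outlier rule and stepwise forward
regression. Also saves a green/blue intensity-vs-TsB scatter plot. Run
01 and 02 first.
"""

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from biliscreen import PipelineConfig, run_report, run_screen

OUT = Path(__file__).resolve().parent.parent / "results" / "run"


def main() -> None:
    cfg = PipelineConfig(out_dir=OUT, seed=1)
    run_screen(cfg)
    run_report(cfg)

    corr = pd.read_csv(OUT / "correlations.csv")
    screening = json.loads((OUT / "screening.json").read_text())
    for _, row in corr.iterrows():
        print(
            f"{row['channel']:>5}: r = {row['r']:.2f} (p = {row['p_value']:.2g}, n = {int(row['n'])})"
        )
    for ch, s in screening.items():
        sens = "n/a" if s["sensitivity"] is None else f"{s['sensitivity']:.1f}%"
        spec = "n/a" if s["specificity"] is None else f"{s['specificity']:.1f}%"
        print(
            f"{ch} limit {s['limit']:.0f}: sensitivity {sens}, specificity {spec}; "
            f"largest 100%-sensitivity limit {s['best_limit_full_sensitivity']}"
        )

    # scatter of the two informative channels against TsB
    intens = pd.read_csv(OUT / "intensities.csv")
    subjects = pd.read_csv(OUT / "cohort.csv")
    raw = intens[intens["aggregation_block"] == 1]
    wide = raw.pivot_table(index="subject_id", columns="channel", values="mean")
    data = wide.merge(subjects, on="subject_id")
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, ch in zip(axes, ("green", "blue")):
        ax.scatter(data[ch], data["tsb_umol_l"], s=18, color=ch)
        ax.set_xlabel(f"{ch} channel mean intensity")
        ax.set_title(ch)
    axes[0].set_ylabel("TsB (umol/L)")
    fig.tight_layout()
    fig.savefig(OUT / "scatter_intensity_tsb.png", dpi=120)
    print(f"wrote {OUT / 'scatter_intensity_tsb.png'} and {OUT / 'report.md'}")


if __name__ == "__main__":
    main()
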