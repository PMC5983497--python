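"""Replicate-cohort calibration study.

Generates 200 independent cohorts of n = 51 under the default profile,
runs the full image-extraction pipeline on each, and reports the mean
channel-TsB Pearson correlation across replicates — the check that the
synthetic study conditions reproduce the intended population correlations
(green 0.59, blue 0.46, red 0.21) and that the red channel stays
non-significant in most cohorts. Writes results/calibration_replicates.csv.
"""

from pathlib import Path

from biliscreen import replicate_correlations
from biliscreen.cohort import CALIBRATION_TARGET_R

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    df = replicate_correlations(n_cohorts=200, n=51, root_seed=1)
    RESULTS.mkdir(exist_ok=True)
    path = RESULTS / "calibration_replicates.csv"
    df.to_csv(path, index=False)
    for ch in ("green", "blue", "red"):
        mean_r = df[f"r_{ch}"].mean()
        print(
            f"{ch:>5}: mean r = {mean_r:.3f} over 200 cohorts "
            f"(target {CALIBRATION_TARGET_R[ch]:.2f}, sd {df[f'r_{ch}'].std():.3f})"
        )
    frac_ns = (df["p_red"] >= 0.05).mean()
    print(f"red channel non-significant (p >= 0.05) in {100 * frac_ns:.0f}% of cohorts")
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
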