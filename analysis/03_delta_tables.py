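"""Baseline-ratio (delta) tables and the cohort summary.

Reads scratch/features.csv (from step 02), computes per-capture deltas
relative to the pre-treatment visit, averages the four points of each
breast, and writes:

  scratch/delta.csv            per-point deltas (inputs to step 04)
  scratch/patient_values.csv   per-breast deltas per patient
  results/delta_summary.csv    cross-patient mean +/- SD per cell

Prints the trajectories of the headline features: treated-side energy
(normal mode) and sum variance (polarized/UV) fall monotonically while
the untreated side moves far less.
"""

from pathlib import Path

import pandas as pd

from derma_radiomics.delta import aggregate_points, delta_ratios, summarize

ROOT = Path(__file__).resolve().parents[1]
TIME_ORDER = ["Before_RT", "RT_D7", "RT_D14", "After_RT_D10"]


def main() -> None:
    features = pd.read_csv(ROOT / "scratch" / "features.csv")
    deltas = delta_ratios(features)
    deltas.to_csv(ROOT / "scratch" / "delta.csv", index=False, float_format="%.8g")
    pv = aggregate_points(deltas)
    pv.to_csv(ROOT / "scratch" / "patient_values.csv", index=False, float_format="%.6g")
    summary = summarize(pv)
    summary.to_csv(ROOT / "results" / "delta_summary.csv", index=False, float_format="%.6g")

    print("delta trajectories (cohort mean +/- SD):")
    for mode, feat in [("normal", "energy"), ("polarized", "sum_variance"), ("uv", "sum_variance")]:
        for side in ("ipsilateral", "contralateral"):
            sub = (
                summary.query("mode == @mode and feature == @feat and side == @side")
                .set_index("timepoint")
                .loc[TIME_ORDER]
            )
            cells = "  ".join(
                f"{m:.3f}±{0.0 if pd.isna(s) else s:.3f}"
                for m, s in zip(sub["mean"], sub["sd"])
            )
            print(f"  {mode:9s} {feat:13s} {side:13s} {cells}")


if __name__ == "__main__":
    main()
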