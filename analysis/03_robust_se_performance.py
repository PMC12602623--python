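"""HC3/HC4 sandwich inference vs classical: type I, power, and SE bias.

Compares the three analytic-SE methods on the one-predictor models across
heteroskedasticity levels, and tabulates each method's mean estimated SE
against the simulated SE (the SD of the estimated slopes), the benchmark
for standard-error bias.

Usage: python analysis/03_robust_se_performance.py [--reps 2000] [--seed 1]
"""

import argparse
from pathlib import Path

import pandas as pd

from hetsim import DISTRIBUTIONS, Scenario, run_scenario, se_bias_table
from hetsim.simulation_harness import summaries_to_frame


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--reps", type=int, default=2000)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    frames = []
    for model in (1, 2, 3):
        for n in (50, 200):
            for g in (0.0, 1.0, 2.0):
                sc = Scenario(model, n, DISTRIBUTIONS["normal"], g,
                              n_reps=args.reps, seed=args.seed)
                summ, _ = run_scenario(sc, ("classical", "HC3", "HC4"))
                frames.append(summaries_to_frame(summ))
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(args.out / "robust_se_performance.csv", index=False)
    bias = se_bias_table(table)
    bias.to_csv(args.out / "se_bias.csv", index=False)

    m1 = table[table["model"] == 1]
    print("Model 1 type-I error by method (rows: n, g):")
    print(m1.pivot_table(index=["n", "g"], columns="method",
                         values="rejection_rate").round(3).to_string())
    print("\nSE ratio mean_se/sd_beta, model 1 (1 = unbiased SE):")
    b1 = bias[bias["model"] == 1]
    print(b1.pivot_table(index=["n", "g"], columns="method",
                         values="se_ratio").round(3).to_string())
    print("\nModel 2 power by method (rows: n, g):")
    m2 = table[table["model"] == 2]
    print(m2.pivot_table(index=["n", "g"], columns="method",
                         values="rejection_rate").round(3).to_string())
    print(
        "\nReading: the classical SE underestimates the simulated SE more "
        "and more as g grows when heteroskedasticity tracks the predictor "
        "of interest (models 1-2), which inflates its type-I error; HC3/HC4 "
        "keep the ratio near 1 and the error near 5% at the cost of power. "
        "When heteroskedasticity tracks the other predictor (model 3), the "
        "classical SE is nearly unbiased for the slope of interest."
    )


if __name__ == "__main__":
    main()
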