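"""Classical OLS inference under assumption violations: type I, coverage, power.

Runs the classical t-test over the one-predictor grid cells that carry the
study's headline findings: type-I inflation growing with heteroskedasticity
severity g (model 1), the matching collapse of 95% CI coverage (model 2),
and the power cost of violations at small n (model 2).

Usage: python analysis/02_classical_performance.py [--reps 2000] [--seed 1]
"""

import argparse
from pathlib import Path

from hetsim import DISTRIBUTIONS, Scenario, run_scenario
from hetsim.simulation_harness import summaries_to_frame


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--reps", type=int, default=2000)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cells = []
    for model in (1, 2):
        for n in (25, 100, 500):
            for g in (0.0, 0.5, 1.0, 2.0):
                cells.append(Scenario(model, n, DISTRIBUTIONS["normal"], g,
                                      n_reps=args.reps, seed=args.seed))
        for dist in ("moderate",):
            for g in (0.0, 2.0):
                cells.append(Scenario(model, 25, DISTRIBUTIONS[dist], g,
                                      n_reps=args.reps, seed=args.seed))

    frames = []
    for sc in cells:
        summ, _ = run_scenario(sc, ("classical",))
        frames.append(summaries_to_frame(summ))
    import pandas as pd

    table = pd.concat(frames, ignore_index=True)
    table.to_csv(args.out / "classical_performance.csv", index=False)

    m1 = table[table["model"] == 1]
    print("Model 1 (true slope 0): classical rejection rate by n and g")
    print(m1.pivot_table(index="n", columns="g",
                         values="rejection_rate").round(3).to_string())
    print("\nModel 2 (true slope 0.8): coverage of the 95% CI by n and g (normal errors)")
    m2 = table[(table["model"] == 2) & (table["distribution"] == "normal")]
    print(m2.pivot_table(index="n", columns="g",
                         values="coverage_rate").round(3).to_string())
    print("\nModel 2 power at n=25 (rows: distribution, cols: g)")
    p25 = table[(table["model"] == 2) & (table["n"] == 25)]
    print(p25.pivot_table(index="distribution", columns="g",
                          values="rejection_rate").round(3).to_string())
    print(
        "\nReading: with heteroskedasticity driven by the predictor of "
        "interest, the classical test's false-positive rate rises far above "
        "5% (and coverage falls equally far below 95%), while power at "
        "small n drops steeply; non-normality alone costs much less."
    )


if __name__ == "__main__":
    main()
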