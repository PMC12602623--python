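"""Run a reduced full grid with all nine methods and emit guidance tables.

This is the end-to-end driver: enumerate a (reduced) factorial grid, run
every method, classify each method per assumption cell against the Bradley
bands, and write the practitioner-facing validity and power matrices.  The
defaults are scaled down (fewer replications and bootstrap draws, two sample
sizes) so the script finishes in minutes; pass a config for the full design.

Usage: python analysis/05_guidance_tables.py [config.yaml] [--reps 400] ...
"""

import argparse
from pathlib import Path

from hetsim import (
    default_grid_config,
    guidance_tables,
    load_config,
    run_grid,
    scenarios_from_config,
)
from hetsim.evaluation_report import render_guidance


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("config", nargs="?", default=None)
    ap.add_argument("--reps", type=int, default=400)
    ap.add_argument("--boot", type=int, default=200)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    if args.config:
        cfg = load_config(args.config)
    else:
        cfg = default_grid_config()
        cfg.update({"ns": [25, 100], "n_reps": args.reps,
                    "B": args.boot, "seed": args.seed})
    scenarios = scenarios_from_config(cfg)
    print(f"running {len(scenarios)} scenarios ...")
    table = run_grid(scenarios, out_dir=args.out / "grid", progress=True)
    table.to_csv(args.out / "grid_summaries.csv", index=False)

    validity, power = guidance_tables(table)
    validity.to_csv(args.out / "guidance_validity.csv", index=False)
    power.to_csv(args.out / "guidance_power.csv", index=False)

    print("\nMethods meeting the STRINGENT validity criterion in every "
          "sub-scenario of each cell:")
    print(render_guidance(validity, "stringent"))
    print("\nMethods meeting at least the LIBERAL validity criterion:")
    print(render_guidance(validity, "liberal"))
    print("\nMethods with power >= .80 across each cell:")
    print(render_guidance(power, "good"))


if __name__ == "__main__":
    main()
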