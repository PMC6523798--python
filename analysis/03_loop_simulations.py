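#!/usr/bin/env python
"""Monte Carlo sweeps of the excluded-volume loop, free and threaded.

Runs the unthreaded sweep used for the scaling fits (N in
{30,50,70,100,150}, T = 100) plus reduced threaded sweeps (w = 1, 2) on
smaller loops, and writes per-condition mean shape descriptors with
block-averaged standard errors to results/shape_sweep.csv.

Run:  python analysis/03_loop_simulations.py [--seed 1] [--frames 600]
"""

from __future__ import annotations

import argparse
from pathlib import Path

import pandas as pd

from lassokit.workbench import (
    SWEEP_LENGTHS,
    SWEEP_LENGTHS_LARGE,
    unthreaded_shape_sweep,
)

THREADED_LENGTHS = (10, 20, 30, 50)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--frames", type=int, default=600,
                    help="decorrelated frames per condition")
    ap.add_argument("--threaded-frames", type=int, default=150)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    tables = []
    lengths = SWEEP_LENGTHS + SWEEP_LENGTHS_LARGE
    print(f"unthreaded sweep N in {lengths} (w=0, T=100)")
    df = unthreaded_shape_sweep(SWEEP_LENGTHS, seed=args.seed,
                                target_frames=args.frames)
    df_large = unthreaded_shape_sweep(SWEEP_LENGTHS_LARGE, seed=args.seed + 17,
                                      target_frames=max(args.frames * 2 // 3, 40))
    import pandas as pd  # noqa: F811
    df = pd.concat([df, df_large], ignore_index=True)
    print(df[["N", "rg", "asphericity", "prolateness", "n_eff"]].to_string(index=False))
    tables.append(df)
    for w in (1, 2):
        print(f"threaded sweep w={w}, N in {THREADED_LENGTHS}")
        dfw = unthreaded_shape_sweep(
            THREADED_LENGTHS, seed=args.seed + w,
            target_frames=args.threaded_frames, w=w,
        )
        print(dfw[["N", "rg", "distension", "asphericity"]].to_string(index=False))
        tables.append(dfw)
    out = pd.concat(tables, ignore_index=True)
    out.to_csv(args.out / "shape_sweep.csv", index=False)
    print("wrote", args.out / "shape_sweep.csv")


if __name__ == "__main__":
    main()
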