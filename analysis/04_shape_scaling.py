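#!/usr/bin/env python
"""Scaling fits of the shape descriptors versus loop length.

Reads results/shape_sweep.csv and fits, for each thread thickness:

  <Rg> = c_r + a_r N^nu        (free nu for w = 0; also fixed nu = 0.59
                                to compare prefactors a_r across w)
  <A>  = A_inf + a_A N^mu
  <P>  = P_inf + a_P N^-0.47

For the unthreaded loop the expected anchors are nu ~ 0.58, A_inf ~
0.071, P_inf ~ 0.33; the threaded prefactor ratio a_r(w)/a_r(0) at fixed
nu is ~1.06 at full statistics (the threaded sweeps here are reduced, so
that ratio is indicative only).

Run:  python analysis/04_shape_scaling.py
"""

from __future__ import annotations

import argparse
from pathlib import Path

import pandas as pd

from lassokit.io import write_json
from lassokit.shapes import (
    FitFailureError,
    fit_asphericity_scaling,
    fit_prolateness_scaling,
    fit_rg_scaling,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--min-n", type=int, default=30)
    args = ap.parse_args()

    df = pd.read_csv(args.results / "shape_sweep.csv")
    report = {}
    a_r0 = None
    for w, sub in df.groupby("w"):
        sub = sub.sort_values("N")
        entry = {}
        try:
            free = fit_rg_scaling(sub["N"], sub["rg"], se=sub["rg_se"],
                                  mode="free", min_n=args.min_n)
            entry["nu"] = free.params["nu"]
        except FitFailureError as err:
            entry["nu_error"] = str(err)
        try:
            fixed = fit_rg_scaling(sub["N"], sub["rg"], se=sub["rg_se"],
                                   mode="fixed", min_n=args.min_n)
            entry["a_r_fixed_nu"] = fixed.params["a_r"]
            entry["c_r_fixed_nu"] = fixed.params["c_r"]
            if w == 0:
                a_r0 = fixed.params["a_r"]
            elif a_r0:
                entry["a_r_ratio_vs_w0"] = fixed.params["a_r"] / a_r0
        except FitFailureError as err:
            entry["a_r_error"] = str(err)
        try:
            fa = fit_asphericity_scaling(sub["N"], sub["asphericity"],
                                         se=sub["asphericity_se"], min_n=args.min_n)
            entry.update({"A_inf": fa.params["A_inf"], "mu": fa.params["mu"]})
        except FitFailureError as err:
            entry["A_error"] = str(err)
        try:
            fp = fit_prolateness_scaling(sub["N"], sub["prolateness"],
                                         se=sub["prolateness_se"], min_n=args.min_n)
            entry.update({"P_inf": fp.params["P_inf"], "a_P": fp.params["a_P"]})
        except FitFailureError as err:
            entry["P_error"] = str(err)
        report[f"w={int(w)}"] = entry
        printable = {k: (round(v, 4) if isinstance(v, float) else v)
                     for k, v in entry.items()}
        print(f"w={int(w)}:", printable)
    write_json(args.results / "scaling_fits.json", report)
    print("wrote", args.results / "scaling_fits.json")


if __name__ == "__main__":
    main()
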