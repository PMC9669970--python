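#!/usr/bin/env python
"""Calibration sweep for the unconstrained readout synaptic strengths.

The integrator-to-readout weight and the recurrent E->E weight are not
fixed by the circuit's printed parameters.  This script runs one ring
integrator, replays it through readout populations over a weight grid,
and reports for each candidate: the number of significantly
time-correlated E cells at p0 = 1.0 and p0 = 0.1, the population-slope
p-values, and the PSR count at p_conn = 0.15/0.25/0.35.  The defaults in
``locint.readout.ReadoutSpec`` were chosen from such a sweep so that the
dense/sparse dissociation is maximal while the stepping regime survives
at moderate recurrence.

Usage:  python scripts/calibrate_readout.py [--seed 1] [--out calibration.tsv]
"""

from __future__ import annotations

import argparse

import pandas as pd

from locint.analysis import bin_rates, count_psr, count_time_correlated, regress_rate_vs_time
from locint.continuous import ContinuousConfig, StimulusSpec, run_continuous_experiment
from locint.readout import GradientSpec, ReadoutSpec, run_single_readout


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--w-int", type=float, nargs="+", default=[0.02, 0.03, 0.05])
    ap.add_argument("--w-ee", type=float, nargs="+", default=[0.05, 0.1, 0.15])
    ap.add_argument("--out", default=None)
    args = ap.parse_args()

    stim = StimulusSpec(alpha=8.0, epochs=((100.0, 600.0),))
    integ = run_continuous_experiment(ContinuousConfig(), stim, 600.0, args.seed)
    rows = []
    for w_int in args.w_int:
        for w_ee in args.w_ee:
            spec = ReadoutSpec(w_integrator_e=w_int, w_integrator_i=w_int, w_e_e=w_ee)
            rec = {"w_int": w_int, "w_ee": w_ee}
            for p0 in (1.0, 0.1):
                r = run_single_readout(integ, GradientSpec(p0=p0), spec, seed=args.seed)
                per = bin_rates(r, 25.0, window=(100.0, 550.0), level="neuron", pop="E")
                pop = bin_rates(r, 25.0, window=(100.0, 550.0), level="population", pop="E")
                slope, p = regress_rate_vs_time(pop)
                rec[f"n_corr_p0_{p0}"] = count_time_correlated(per)
                rec[f"slope_p0_{p0}"] = round(slope, 4)
                rec[f"p_p0_{p0}"] = float(f"{p:.2e}")
            grid = {}
            for pc in (0.15, 0.25, 0.35):
                r = run_single_readout(integ, GradientSpec(p0=0.1), spec,
                                       seed=args.seed, p_conn=pc)
                grid[(0.1, pc)] = bin_rates(r, 50.0, window=(100.0, 550.0),
                                            level="neuron", pop="E")
            tab = count_psr(grid)
            for pc in (0.15, 0.25, 0.35):
                rec[f"psr_pc_{pc}"] = int(tab[tab.p_conn == pc].psr_count.iloc[0])
            rows.append(rec)
            print(rec, flush=True)
    df = pd.DataFrame(rows)
    if args.out:
        df.to_csv(args.out, sep="\t", index=False)


if __name__ == "__main__":
    main()
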