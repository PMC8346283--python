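#!/usr/bin/env python
"""Fit the voltage dependence of activation for each simulated family.

Reads the current families written by 01_simulate_recordings.py,
applies P/4 leak subtraction, extrapolates steady-state currents from
exponential-with-delay fits, converts to chord conductances against the
Nernst reversal potential, and fits the Boltzmann G-V plus the
exponential foot (threshold voltage).  Writes results/gv_fits.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from hvkit.io import read_family
from hvkit.pipeline import analyze_family


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--in-dir", type=Path, default=Path("results/synthetic"))
    parser.add_argument("--out", type=Path, default=Path("results/gv_fits.csv"))
    args = parser.parse_args()

    records = []
    paths = [
        p for p in sorted(args.in_dir.glob("family_ph*.tsv"))
        if not p.stem.endswith("_p4")  # subsweep companions of the main tables
    ]
    for path in paths:
        record = analyze_family(read_family(path))
        record["source"] = path.name
        records.append(record)
        print(
            f"{path.name}: delta pH {record['delta_pH']:+g} -> "
            f"V_half = {record['V_half_mV']:.2f} +/- {record['V_half_se_mV']:.2f} mV, "
            f"q = {record['q_e0']:.3f} e0, V_thr = {record['V_thr_mV']:.2f} mV"
        )
    if not records:
        raise SystemExit(f"no family tables found in {args.in_dir}")
    args.out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(records).to_csv(args.out, index=False)
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
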