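#!/usr/bin/env python
"""Compare the fitted half-activation voltages with the allosteric model.

Reads the per-family fits from 02_fit_voltage_dependence.py, evaluates
the coral allosteric parameter set at the same pH conditions, reports
per-condition residuals and the summary RMS, and writes a dense model
sweep of V_half versus delta pH (pH_o fixed at 7) showing the steep
limb (> 40 mV per pH unit) and the saturation plateaus.
Writes results/model_comparison.csv and results/model_sweep.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from hvkit.gating import AMHV1_SCHEME_I, ProtonEnvironment, v_half_vs_delta_ph
from hvkit.pipeline import compare_model_to_vhalf


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--fits", type=Path, default=Path("results/gv_fits.csv"))
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    fits = pd.read_csv(args.fits).sort_values("delta_pH", ignore_index=True)
    residuals, rms = compare_model_to_vhalf(fits, AMHV1_SCHEME_I)
    for row in residuals.itertuples():
        print(
            f"delta pH {row.delta_pH:+g}: measured {row.V_half_measured_mV:.2f} mV, "
            f"model {row.V_half_model_mV:.2f} mV, residual {row.residual_mV:+.2f} mV"
        )
    print(f"RMS deviation from the model: {rms:.3f} mV")

    sweep = v_half_vs_delta_ph(
        AMHV1_SCHEME_I,
        [ProtonEnvironment(7.0, p) for p in np.arange(-2.0, 18.01, 0.1)],
    ).sort_values("delta_pH", ignore_index=True)
    slope = np.gradient(sweep["V_half_mV"].to_numpy(), sweep["delta_pH"].to_numpy())
    print(
        f"model sweep: plateaus at {sweep['V_half_mV'].iloc[0]:.1f} and "
        f"{sweep['V_half_mV'].iloc[-1]:.1f} mV, "
        f"max |slope| {np.max(np.abs(slope)):.1f} mV per pH unit"
    )

    args.out_dir.mkdir(parents=True, exist_ok=True)
    residuals.to_csv(args.out_dir / "model_comparison.csv", index=False)
    sweep.to_csv(args.out_dir / "model_sweep.csv", index=False)
    print(f"wrote {args.out_dir / 'model_comparison.csv'} and model_sweep.csv")


if __name__ == "__main__":
    main()
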