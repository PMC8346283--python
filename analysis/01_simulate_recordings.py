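#!/usr/bin/env python
"""Simulate the synthetic study inputs.

Writes, under results/synthetic/:
  * four step-depolarization current families (pH_i 8..5 at pH_o 7,
    i.e. delta pH -1..2) generated from the coral allosteric gating
    model with P/4 subsweeps, 0.5 nS leak and 2 pA noise;
  * a tail-current family at delta pH 1 for reversal measurement;
  * a zinc-block experiment (control + 10 uM-style blocked family and a
    1..1000 uM dose table);
  * a 134-cell FRET population table.
"""

import argparse
from pathlib import Path

import numpy as np

from hvkit import (
    AMHV1_SCHEME_I,
    DimerFretModel,
    GeneratorConfig,
    ProtonEnvironment,
    VoltageProtocol,
    WoodhullBlock,
    generate_block_experiment,
    generate_current_family,
    generate_fret_population,
    generate_tail_family,
)
from hvkit.io import write_family


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out-dir", type=Path, default=Path("results/synthetic"))
    args = parser.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    proto = VoltageProtocol(
        holding_mV=-60.0,
        test_mV=tuple(np.arange(-60.0, 141.0, 10.0)),
        duration_ms=500.0,
        dt_ms=1.0,
        p4_subsweeps=4,
        p4_holding_mV=-80.0,
    )
    for k, ph_i in enumerate((8.0, 7.0, 6.0, 5.0)):
        cfg = GeneratorConfig(
            gating=AMHV1_SCHEME_I,
            env=ProtonEnvironment(7.0, ph_i),
            protocol=proto,
            g_max_nS=5.0,
            g_leak_nS=0.5,
            noise_sd_pA=2.0,
            seed=args.seed + k,
        )
        fam = generate_current_family(cfg)
        write_family(fam, out / f"family_ph{ph_i:g}.tsv")
        print(f"wrote family at pH_o 7 / pH_i {ph_i:g} (delta pH {7 - ph_i:+g})")

    tails = generate_tail_family(
        GeneratorConfig(env=ProtonEnvironment(7.0, 6.0), noise_sd_pA=1.0,
                        seed=args.seed + 10),
        tail_potentials=np.arange(-100.0, -19.0, 10.0),
    )
    write_family(tails, out / "tails_dph1.tsv")
    print("wrote tail family (delta pH 1, Nernst reversal -58.6 mV)")

    block_proto = VoltageProtocol(
        holding_mV=-80.0, test_mV=tuple(np.arange(-80.0, 141.0, 20.0)),
        duration_ms=500.0, dt_ms=1.0,
    )
    control, blocked, dose = generate_block_experiment(
        GeneratorConfig(protocol=block_proto, seed=args.seed + 20),
        woodhull=WoodhullBlock(delta=0.19, V_half_mV=77.6, z=2.0),
        hill=(27.4, 0.48),
        concentrations_uM=np.logspace(0.0, 3.0, 12),
    )
    write_family(control, out / "zinc_control.tsv")
    write_family(blocked, out / "zinc_blocked.tsv")
    dose.to_csv(out / "zinc_dose_response.csv", index=False)
    print("wrote zinc block experiment (control, blocked, dose table)")

    pop = generate_fret_population(
        134, DimerFretModel(E_max=0.347, rho=1.0, R0=54.0),
        noise_sd=0.02, seed=args.seed + 30,
    )
    import pandas as pd

    pd.DataFrame(
        [{"I_d": s.I_d, "I_a": s.I_a, "E_app": s.E_app} for s in pop]
    ).to_csv(out / "fret_cells.csv", index=False)
    print("wrote 134-cell FRET population")


if __name__ == "__main__":
    main()
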