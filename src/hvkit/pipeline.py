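"""End-to-end study orchestration.

``run_pipeline`` executes the full analysis chain on a set of recordings
(simulated from a config block, or loaded from trace tables): P/4 leak
subtraction, per-trace activation fits, conductance extraction against
the Nernst reversal potential, Boltzmann and threshold fits per pH
condition, assembly of the V_half / V_Thr versus delta-pH table, and
comparison with the allosteric gating model.  Stages are logged and the
result bundle is written as delimited tables plus a JSON summary; the
whole run is a deterministic function of the config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .constants import DEFAULT_TEMPERATURE_K
from .ephys import (
    CurrentFamily,
    VoltageProtocol,
    conductance_from_iv,
    fit_activation_trace,
    fit_boltzmann,
    fit_threshold,
    nernst_potential,
    p4_leak_subtract,
)
from .gating import (
    AllostericParams,
    PRESETS,
    ProtonEnvironment,
    v_half_vs_delta_ph,
)
from .io import read_family, write_family, write_records
from .simulate import ActivationKinetics, BoltzmannGating, GeneratorConfig, generate_current_family

logger = logging.getLogger(__name__)

__all__ = ["StudyResult", "run_pipeline", "compare_model_to_vhalf", "analyze_family"]


@dataclass
class StudyResult:
    """Bundle of everything a study run produces."""

    fit_records: list[dict]
    vhalf_table: pd.DataFrame
    model_table: Optional[pd.DataFrame]
    residuals: Optional[pd.DataFrame]
    rms_mV: Optional[float]
    provenance: dict


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _gating_from_config(block: dict):
    if "preset" in block:
        return PRESETS[block["preset"]]
    if "allosteric" in block:
        return AllostericParams.from_dict(block["allosteric"])
    if "boltzmann" in block:
        return BoltzmannGating(**block["boltzmann"])
    raise ValueError("gating config needs 'preset', 'allosteric' or 'boltzmann'")


def _protocol_from_config(block: dict) -> VoltageProtocol:
    block = dict(block)
    if "test_range" in block:
        lo, hi, step = block.pop("test_range")
        block["test_mV"] = tuple(np.arange(lo, hi + step / 2, step))
    else:
        block["test_mV"] = tuple(block["test_mV"])
    return VoltageProtocol(**block)


def _steady_state_current(time_ms, trace) -> tuple[float, float]:
    """(I_ss, standard error) for one trace: exponential-with-delay
    extrapolation where the trace is clearly relaxing (sign-aware, so
    inward currents below the reversal potential work too), otherwise
    the late-pulse mean."""
    n = max(1, len(trace) // 20)
    late = float(np.mean(trace[-n:]))
    sign = 1.0 if late >= 0 else -1.0
    try:
        act = fit_activation_trace(time_ms, sign * trace)
        return sign * act.I_ss_pA, float(np.sqrt(act.covariance[0, 0]))
    except (ValueError, RuntimeError):
        se = float(np.std(trace[-n:], ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        return late, se


def analyze_family(
    family: CurrentFamily,
    threshold_fraction: float = 0.1,
    guard_mV: float = 5.0,
) -> dict:
    """Analyze one recording: leak subtraction (if subsweeps are
    present), steady-state currents by exponential-with-delay
    extrapolation, chord conductances against the Nernst reversal
    potential, Boltzmann and exponential-foot fits.

    Test potentials within ``guard_mV`` of the reversal potential are
    dropped (the chord conductance I/(V - V_rev) is ill-conditioned
    there), and conductance points are weighted by the propagated
    steady-state current uncertainty when it is available.

    Returns a flat record with the fitted parameters and their standard
    errors; used both by :func:`run_pipeline` and directly in scripts.
    """
    if family.subsweeps is not None:
        family = p4_leak_subtract(family)
    env = family.environment
    temperature = family.temperature
    v_rev = float(family.metadata.get("V_rev_mV", nernst_potential(env, temperature)))

    currents: dict[float, tuple[float, float]] = {}
    for v, trace in family.traces.items():
        if abs(v - v_rev) < guard_mV:
            logger.info("skipping %s mV (within guard of V_rev)", v)
            continue
        currents[v] = _steady_state_current(family.time_ms, trace)

    volts = np.array(sorted(currents))
    iv = np.array([currents[v][0] for v in volts])
    iv_se = np.array([currents[v][1] for v in volts])
    use_sem = bool(np.all(np.isfinite(iv_se)) and np.all(iv_se > 0))
    gv_raw = conductance_from_iv(
        volts, iv, v_rev, guard_mV=min(guard_mV, 1.0),
        sem_pA=iv_se if use_sem else None,
    )
    bfit = fit_boltzmann(gv_raw, temperature)
    # normalize by the fitted G_max (robust to incomplete saturation)
    gv_norm = conductance_from_iv(
        volts, iv / bfit.G_max, v_rev, guard_mV=min(guard_mV, 1.0)
    )
    gv_norm.normalized = True
    tfit = fit_threshold(gv_norm, fraction=threshold_fraction, temperature=temperature)
    return {
        "pH_o": env.pH_o,
        "pH_i": env.pH_i,
        "delta_pH": env.delta_ph,
        "V_rev_mV": v_rev,
        "V_half_mV": bfit.V_half_mV,
        "V_half_se_mV": bfit.V_half_stderr,
        "q_e0": bfit.q_e0,
        "q_se_e0": bfit.q_stderr,
        "G_max_nS": bfit.G_max,
        "V_thr_mV": tfit.V_thr_mV,
        "q_foot_e0": tfit.q_e0,
    }


def compare_model_to_vhalf(
    table: pd.DataFrame,
    params: AllostericParams,
    ph_pairs: Optional[Sequence[ProtonEnvironment]] = None,
) -> tuple[pd.DataFrame, float]:
    """Residuals of measured half-activation voltages against the
    allosteric-model prediction at the same pH conditions.

    ``table`` needs columns ``pH_o``, ``pH_i`` and ``V_half_mV``; the
    model is evaluated at ``ph_pairs`` (default: the table's own
    conditions, which must then match row for row).  Returns the
    residual table and the summary RMS in mV.
    """
    if ph_pairs is None:
        ph_pairs = [
            ProtonEnvironment(row.pH_o, row.pH_i) for row in table.itertuples()
        ]
    if len(ph_pairs) != len(table):
        raise ValueError(
            f"{len(ph_pairs)} model conditions for {len(table)} measured rows"
        )
    model = v_half_vs_delta_ph(params, list(ph_pairs))
    residual = table["V_half_mV"].to_numpy() - model["V_half_mV"].to_numpy()
    out = pd.DataFrame(
        {
            "delta_pH": model["delta_pH"],
            "V_half_measured_mV": table["V_half_mV"].to_numpy(),
            "V_half_model_mV": model["V_half_mV"],
            "residual_mV": residual,
        }
    )
    rms = float(np.sqrt(np.mean(residual**2)))
    return out, rms


def run_pipeline(
    config: dict | str | Path,
    out_dir: Optional[str | Path] = None,
    seed: Optional[int] = None,
) -> StudyResult:
    """Run the full study described by ``config`` (mapping, or a path to
    a YAML document with sections ``inputs`` / ``simulate`` / ``fits`` /
    ``model``).

    ``simulate`` holds a gating source, protocol, conductances, noise
    and a list of pH ``conditions``; alternatively ``inputs`` lists
    trace-table paths.  ``seed`` overrides the configured seed.  When
    ``out_dir`` is given, per-recording fit records, the assembled
    V_half table and the model comparison are written there.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    cfg_hash = _config_hash(config)
    logger.info("pipeline start (config %s)", cfg_hash)

    families: list[CurrentFamily] = []
    if "simulate" in config:
        sim = config["simulate"]
        gating = _gating_from_config(sim["gating"])
        protocol = _protocol_from_config(sim["protocol"])
        kinetics = ActivationKinetics(**sim.get("kinetics", {}))
        base_seed = seed if seed is not None else int(sim.get("seed", 0))
        for k, cond in enumerate(sim["conditions"]):
            env = ProtonEnvironment(cond["pH_o"], cond["pH_i"])
            gen = GeneratorConfig(
                gating=gating,
                env=env,
                kinetics=kinetics,
                protocol=protocol,
                g_max_nS=float(sim.get("g_max_nS", 5.0)),
                g_leak_nS=float(sim.get("g_leak_nS", 0.0)),
                noise_sd_pA=float(sim.get("noise_sd_pA", 0.0)),
                temperature_K=float(sim.get("temperature_K", DEFAULT_TEMPERATURE_K)),
                seed=base_seed + k,
            )
            logger.info("simulating condition pH_o=%s pH_i=%s", env.pH_o, env.pH_i)
            families.append(generate_current_family(gen))
    elif "inputs" in config and config["inputs"]:
        for path in config["inputs"]:
            logger.info("loading %s", path)
            families.append(read_family(path))
    else:
        raise ValueError("config must provide a 'simulate' block or 'inputs' list")

    fits_cfg = config.get("fits", {})
    records = [
        analyze_family(
            fam,
            threshold_fraction=float(fits_cfg.get("threshold_fraction", 0.1)),
            guard_mV=float(fits_cfg.get("guard_mV", 1.0)),
        )
        for fam in families
    ]
    vhalf = (
        pd.DataFrame(records)
        .groupby(["delta_pH", "pH_o", "pH_i"], as_index=False)
        .agg(
            V_half_mV=("V_half_mV", "mean"),
            V_half_sem_mV=("V_half_mV", lambda x: x.sem() if len(x) > 1 else x.iloc[0] * 0),
            V_half_se_mV=("V_half_se_mV", "mean"),
            V_thr_mV=("V_thr_mV", "mean"),
            q_e0=("q_e0", "mean"),
        )
        .sort_values("delta_pH", ignore_index=True)
    )

    model_table = residuals = None
    rms = None
    if "model" in config:
        params = _gating_from_config(config["model"])
        if not isinstance(params, AllostericParams):
            raise ValueError("model comparison requires an allosteric parameter set")
        residuals, rms = compare_model_to_vhalf(vhalf, params)
        model_table = residuals[["delta_pH", "V_half_model_mV"]]
        logger.info("model comparison RMS %.3f mV", rms)

    provenance = {
        "config_hash": cfg_hash,
        "seed": seed,
        "hvkit_version": __version__,
        "n_recordings": len(families),
    }
    result = StudyResult(
        fit_records=records,
        vhalf_table=vhalf,
        model_table=model_table,
        residuals=residuals,
        rms_mV=rms,
        provenance=provenance,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_records(records, out_dir / "fit_records.json")
        vhalf.to_csv(out_dir / "vhalf_vs_delta_ph.csv", index=False)
        if residuals is not None:
            residuals.to_csv(out_dir / "model_comparison.csv", index=False)
        summary = {**provenance, "rms_mV": rms}
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
        logger.info("results written to %s", out_dir)
    return result
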