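"""Forward simulation of patch-clamp proton-current recordings.

The generator composes the same physics the analysis modules invert:
steady-state channel current I_ss(V) = G_max * P_open(V) * (V - V_rev)
with an ohmic driving force and a Nernstian proton reversal potential,
an exponential-with-delay activation time course whose tau(V) and
delta(V) fall e-fold per V_T/q of depolarization, a linear leak
referenced to the holding potential, white Gaussian recording noise,
optional P/4 leak-estimation subsweeps, and optional zinc block applied
as a Woodhull (per-voltage) or Hill (per-concentration) factor.

Every generator is a deterministic function of its configuration and
seed, so analysis round trips are exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE_K, thermal_voltage_mv
from .ephys import CurrentFamily, VoltageProtocol, boltzmann_conductance, nernst_potential
from .gating import AllostericParams, ProtonEnvironment, open_probability
from .block import hill_fraction, woodhull_fraction
from .fret import DimerFretModel, FretSample, dimer_eapp

__all__ = [
    "BoltzmannGating",
    "ActivationKinetics",
    "WoodhullBlock",
    "HillBlock",
    "GeneratorConfig",
    "generate_current_family",
    "generate_tail_family",
    "generate_block_experiment",
    "generate_fret_population",
]


@dataclass(frozen=True)
class BoltzmannGating:
    """Two-state gating source: P_open(V) = 1/(1 + exp(-q(V - V_half)/V_T))."""

    V_half_mV: float
    q_e0: float

    def p_open(self, V, temperature: float, env: ProtonEnvironment):
        return boltzmann_conductance(V, self.V_half_mV, self.q_e0, 1.0, temperature)


GatingSource = Union[BoltzmannGating, AllostericParams]


def _p_open(source: GatingSource, V, temperature: float, env: ProtonEnvironment):
    if isinstance(source, AllostericParams):
        return open_probability(source.with_temperature(temperature), V, env)
    return source.p_open(V, temperature, env)


@dataclass(frozen=True)
class ActivationKinetics:
    """Voltage-dependent activation kinetics: k(V) = k(0)*exp(-V*q_k/V_T)
    for both the time constant tau and the delay delta."""

    tau0_ms: float = 212.0
    q_tau_e0: float = 0.37
    delta0_ms: float = 98.2
    q_delta_e0: float = 0.47

    def tau(self, V, temperature: float):
        vt = thermal_voltage_mv(temperature)
        return self.tau0_ms * np.exp(-np.asarray(V, float) * self.q_tau_e0 / vt)

    def delta(self, V, temperature: float):
        vt = thermal_voltage_mv(temperature)
        return self.delta0_ms * np.exp(-np.asarray(V, float) * self.q_delta_e0 / vt)


@dataclass(frozen=True)
class WoodhullBlock:
    delta: float
    V_half_mV: float
    z: float = 2.0


@dataclass(frozen=True)
class HillBlock:
    KD_uM: float
    n: float
    conc_uM: float


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything needed to simulate one recording.

    Defaults describe a coral-type proton channel recorded at 22 C under
    a one-unit pH gradient (pH_o 7 / pH_i 6): near-Boltzmann activation
    with midpoint ~8 mV and apparent charge ~2 e0, activation time
    constants of a couple hundred ms at 0 mV, a reversal potential on
    the proton Nernst line, and a few pA of recording noise.
    """

    gating: GatingSource = BoltzmannGating(V_half_mV=7.85, q_e0=2.09)
    env: ProtonEnvironment = ProtonEnvironment(pH_o=7.0, pH_i=6.0)
    kinetics: ActivationKinetics = ActivationKinetics()
    protocol: VoltageProtocol = VoltageProtocol(
        holding_mV=-60.0,
        test_mV=tuple(np.arange(-50.0, 61.0, 10.0)),
        duration_ms=500.0,
        dt_ms=1.0,
    )
    g_max_nS: float = 5.0
    g_leak_nS: float = 0.0
    noise_sd_pA: float = 0.0
    reversal_mV: Optional[float] = None  # None -> Nernst from env
    temperature_K: float = DEFAULT_TEMPERATURE_K
    block: Optional[Union[WoodhullBlock, HillBlock]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_pA < 0 or self.g_max_nS < 0 or self.g_leak_nS < 0:
            raise ValueError("noise and conductances must be non-negative")

    @property
    def v_rev_mV(self) -> float:
        if self.reversal_mV is not None:
            return self.reversal_mV
        return nernst_potential(self.env, self.temperature_K)

    def metadata(self) -> dict:
        return {
            "pH_o": self.env.pH_o,
            "pH_i": self.env.pH_i,
            "temperature_K": self.temperature_K,
            "configuration": "whole-cell",
            "V_rev_mV": self.v_rev_mV,
            "seed": self.seed,
        }


def _channel_trace(t, i_ss, tau, delta):
    """Exponential-with-delay activation; exactly zero before the delay."""
    trace = np.zeros_like(t)
    late = t > delta
    trace[late] = i_ss * (1.0 - np.exp(-(t[late] - delta) / tau))
    return trace


def _block_factor(config: GeneratorConfig, V: float) -> float:
    if config.block is None:
        return 1.0
    if isinstance(config.block, WoodhullBlock):
        fb = woodhull_fraction(
            V, config.block.delta, config.block.z,
            config.block.V_half_mV, config.temperature_K,
        )
    else:
        fb = hill_fraction(config.block.conc_uM, config.block.KD_uM, config.block.n)
    return 1.0 - float(fb)


def generate_current_family(config: GeneratorConfig) -> CurrentFamily:
    """Simulate a step-depolarization current family.

    Currents are holding-baseline-referenced: leak contributes
    g_leak*(V - holding) and the channel component rises toward
    G_max * P_open(V) * (V - V_rev) with the configured kinetics.  When
    the protocol requests P/4 subsweeps they are generated from the
    sub-threshold ``p4_holding_mV`` level (leak only), each with its own
    noise realization.
    """
    rng = np.random.default_rng(config.seed)
    proto = config.protocol
    t = proto.time_base()
    v_rev = config.v_rev_mV
    traces: dict[float, np.ndarray] = {}
    subsweeps: Optional[dict[float, list[np.ndarray]]] = (
        {} if proto.p4_subsweeps > 0 else None
    )
    for V in proto.test_mV:
        p = _p_open(config.gating, V, config.temperature_K, config.env)
        i_ss = config.g_max_nS * p * (V - v_rev) * _block_factor(config, V)
        tau = float(config.kinetics.tau(V, config.temperature_K))
        delta = float(config.kinetics.delta(V, config.temperature_K))
        trace = _channel_trace(t, i_ss, tau, delta)
        trace = trace + config.g_leak_nS * (V - proto.holding_mV)
        if config.noise_sd_pA > 0:
            trace = trace + rng.normal(0.0, config.noise_sd_pA, size=t.shape)
        traces[float(V)] = trace
        if subsweeps is not None:
            n = proto.p4_subsweeps
            step = (V - proto.holding_mV) / n  # delivered from the sub-threshold level
            subs = []
            for _ in range(n):
                sub = np.full_like(t, config.g_leak_nS * step)
                if config.noise_sd_pA > 0:
                    sub = sub + rng.normal(0.0, config.noise_sd_pA, size=t.shape)
                subs.append(sub)
            subsweeps[float(V)] = subs
    return CurrentFamily(
        protocol=proto,
        time_ms=t,
        traces=traces,
        metadata=config.metadata(),
        subsweeps=subsweeps,
    )


def generate_tail_family(
    config: GeneratorConfig,
    tail_potentials: Sequence[float],
    prepulse_mV: float = 60.0,
    prepulse_ms: float = 500.0,
    tail_duration_ms: float = 50.0,
    tail_tau_ms: float = 10.0,
) -> CurrentFamily:
    """Simulate a tail-current protocol for reversal-potential measurement.

    An activating prepulse opens channels to P(prepulse); the membrane
    then steps to each tail potential, where the instantaneous current
    G_max * P(prepulse) * (V_tail - V_rev) decays mono-exponentially with
    the configured tail time constant (deactivation; an instantaneous
    jump followed by relaxation).  The instantaneous tail I-V crosses
    zero at the reversal potential.
    """
    rng = np.random.default_rng(config.seed + 1)
    t = np.arange(0.0, tail_duration_ms, config.protocol.dt_ms)
    p_pre = _p_open(config.gating, prepulse_mV, config.temperature_K, config.env)
    v_rev = config.v_rev_mV
    traces: dict[float, np.ndarray] = {}
    for V in tail_potentials:
        i0 = config.g_max_nS * p_pre * (V - v_rev)
        trace = i0 * np.exp(-t / tail_tau_ms)
        if config.noise_sd_pA > 0:
            trace = trace + rng.normal(0.0, config.noise_sd_pA, size=t.shape)
        traces[float(V)] = trace
    proto = VoltageProtocol(
        holding_mV=prepulse_mV,
        test_mV=tuple(float(v) for v in tail_potentials),
        duration_ms=tail_duration_ms,
        dt_ms=config.protocol.dt_ms,
    )
    meta = config.metadata()
    meta.update({"prepulse_mV": prepulse_mV, "prepulse_ms": prepulse_ms,
                 "protocol_kind": "tail"})
    return CurrentFamily(protocol=proto, time_ms=t, traces=traces, metadata=meta)


def generate_block_experiment(
    config: GeneratorConfig,
    woodhull: Optional[WoodhullBlock] = None,
    hill: Optional[tuple[float, float]] = None,
    concentrations_uM: Optional[Sequence[float]] = None,
) -> tuple[CurrentFamily, CurrentFamily, Optional[pd.DataFrame]]:
    """Simulate a zinc-block experiment.

    Returns ``(control_family, blocked_family, dose_table)``.  The
    blocked family applies the Woodhull factor 1 - F_B(V) to the control
    currents (same seed, so noise-free configurations differ only by the
    block factor).  When ``hill=(KD_uM, n)`` and concentrations are
    given, a dose-response table with columns ``conc_uM`` and
    ``fraction_blocked`` is produced as well.
    """
    control = generate_current_family(replace(config, block=None))
    blocked = generate_current_family(replace(config, block=woodhull))
    dose = None
    if hill is not None:
        if concentrations_uM is None or len(concentrations_uM) == 0:
            raise ValueError("Hill dose-response requested without concentrations")
        kd, n = hill
        conc = np.asarray(concentrations_uM, dtype=float)
        fb = np.where(conc > 0, hill_fraction(np.maximum(conc, 1e-300), kd, n), 0.0)
        dose = pd.DataFrame({"conc_uM": conc, "fraction_blocked": fb})
    return control, blocked, dose


def generate_fret_population(
    n_cells: int,
    model: DimerFretModel,
    ratio_logmean: float = 0.0,
    ratio_logsd: float = 0.75,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> list[FretSample]:
    """Simulate a population of cells for dimer-stoichiometry FRET.

    Per cell the donor/acceptor expression ratio is lognormal
    (``exp(N(ratio_logmean, ratio_logsd))``, spanning acceptor- to
    donor-dominated cells), E_app is the dimer-model prediction plus
    Gaussian measurement noise, and the acceptor intensity is drawn from
    a broad lognormal so (I_d, I_a) reproduce the ratio exactly.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if ratio_logsd <= 0 or noise_sd < 0:
        raise ValueError("invalid distribution parameters")
    rng = np.random.default_rng(seed)
    ratios = np.exp(rng.normal(ratio_logmean, ratio_logsd, size=n_cells))
    i_a = np.exp(rng.normal(math.log(1000.0), 0.3, size=n_cells))
    eapp = dimer_eapp(ratios, model)
    if noise_sd > 0:
        eapp = eapp + rng.normal(0.0, noise_sd, size=n_cells)
    return [
        FretSample(I_d=float(r * a), I_a=float(a), E_app=float(e))
        for r, a, e in zip(ratios, i_a, eapp)
    ]
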