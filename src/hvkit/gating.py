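"""Equilibrium allosteric model of voltage- and pH-dependent proton-channel gating.

The channel is described by an eight-state MWC-style scheme: a single
voltage-dependent closed/open transition with equilibrium constant
``K(V) = Kv0 * exp(q_g * V / V_T)``, allosterically coupled to two
saturable proton-binding sites, one facing the extracellular solution
(titration weight ``x_o = 10**(pK_o - pH_o)``) and one facing the
cytoplasm (``x_i = 10**(pK_i - pH_i)``).  Three dimensionless coupling
constants bias the equilibrium: C links external protonation to opening
(C < 1 makes external protons inhibitory), D links internal protonation
to opening (D > 1 makes internal protons excitatory), and E couples the
two sites to each other in both conformations.

Every state weight is taken relative to the unliganded closed state, so
the closed tier carries weights ``{1, x_o, x_i, E*x_o*x_i}`` and the open
tier ``K(V) * {1, C*x_o, D*x_i, C*D*E*x_o*x_i}``.  Because the weights
are state functions, detailed balance around every loop of the scheme
holds by construction.  The open probability is the ratio of the open
tier to the full partition function and is therefore an exact Boltzmann
function of voltage with slope charge q_g; the pH gradient only moves
its midpoint.

All voltages are in mV, temperatures in kelvin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import logsumexp

from .constants import DEFAULT_TEMPERATURE_K, LN10, thermal_voltage_mv

__all__ = [
    "AllostericParams",
    "ProtonEnvironment",
    "StateWeights",
    "AMHV1_SCHEME_I",
    "PRESETS",
    "binding_weight",
    "state_weights",
    "open_probability",
    "solve_v_half",
    "solve_v_threshold",
    "v_half_vs_delta_ph",
]


@dataclass(frozen=True)
class AllostericParams:
    """Parameter set of the eight-state allosteric gating scheme.

    Parameters
    ----------
    Kv0 : float
        Closed->open equilibrium constant at 0 mV (dimensionless, > 0).
    q_g : float
        Gating charge of the opening transition, elementary charges.
    C : float
        Coupling of the external proton site to opening (> 0; < 1 inhibitory).
    D : float
        Coupling of the internal proton site to opening (> 0; > 1 excitatory).
    E : float
        Coupling between the two proton sites (> 0), applied in both
        conformations.
    pK_o, pK_i : float
        Acid-dissociation exponents of the external and internal sites.
    temperature : float
        Temperature in kelvin; sets the thermal voltage.
    """

    Kv0: float
    q_g: float
    C: float
    D: float
    E: float
    pK_o: float
    pK_i: float
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        for name in ("Kv0", "C", "D", "E", "temperature"):
            value = getattr(self, name)
            if not (value > 0 and math.isfinite(value)):
                raise ValueError(f"{name} must be positive and finite, got {value}")
        if self.q_g == 0 or not math.isfinite(self.q_g):
            raise ValueError(f"q_g must be nonzero and finite, got {self.q_g}")

    @property
    def thermal_voltage(self) -> float:
        return thermal_voltage_mv(self.temperature)

    def to_dict(self) -> dict:
        """Flat config mapping (key ``temperature_K`` for the temperature)."""
        return {
            "Kv0": self.Kv0,
            "q_g": self.q_g,
            "C": self.C,
            "D": self.D,
            "E": self.E,
            "pK_o": self.pK_o,
            "pK_i": self.pK_i,
            "temperature_K": self.temperature,
        }

    @classmethod
    def from_dict(cls, config: dict) -> "AllostericParams":
        cfg = dict(config)
        if "temperature_K" in cfg:
            cfg["temperature"] = cfg.pop("temperature_K")
        return cls(**cfg)

    def with_temperature(self, temperature_k: float) -> "AllostericParams":
        return replace(self, temperature=temperature_k)


#: Parameter set describing the coral (Acropora millepora) Hv1 channel.
AMHV1_SCHEME_I = AllostericParams(
    Kv0=5e-5, q_g=1.0, C=2e-4, D=1e5, E=5e5, pK_o=3.4, pK_i=7.0
)

PRESETS: dict[str, AllostericParams] = {"amhv1": AMHV1_SCHEME_I}


@dataclass(frozen=True)
class ProtonEnvironment:
    """The pH on either face of the membrane.

    ``delta_ph`` follows the electrophysiology convention pH_o - pH_i: a
    positive gradient (alkaline outside) favors outward proton flux and
    left-shifts activation.
    """

    pH_o: float
    pH_i: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.pH_o) and math.isfinite(self.pH_i)):
            raise ValueError("pH values must be finite")

    @property
    def delta_ph(self) -> float:
        return self.pH_o - self.pH_i


@dataclass(frozen=True)
class StateWeights:
    """Statistical weights of the eight gating states, relative to the
    unliganded closed state (whose weight is exactly 1).

    Naming: ``c``/``o`` for closed/open, suffixes ``_ho``, ``_hi``,
    ``_hohi`` for external, internal and double proton occupancy.
    """

    c: float = 1.0
    c_ho: float = 0.0
    c_hi: float = 0.0
    c_hohi: float = 0.0
    o: float = 0.0
    o_ho: float = 0.0
    o_hi: float = 0.0
    o_hohi: float = 0.0

    def closed(self) -> np.ndarray:
        return np.array([self.c, self.c_ho, self.c_hi, self.c_hohi])

    def open(self) -> np.ndarray:
        return np.array([self.o, self.o_ho, self.o_hi, self.o_hohi])

    def partition(self) -> tuple[float, float]:
        """(closed-tier sum, open-tier sum)."""
        return float(self.closed().sum()), float(self.open().sum())

    def open_probability(self) -> float:
        zc, zo = self.partition()
        return zo / (zc + zo)


def binding_weight(pK: float, pH: float) -> float:
    """Equilibrium weight of the protonated state of a single titratable
    site relative to its unprotonated state, ``10**(pK - pH)``.

    Equals 1 at pH = pK (half protonation) and grows tenfold per pH unit
    of acidification.
    """
    return 10.0 ** (pK - pH)


def _log_tier_weights(
    params: AllostericParams, V: float, env: ProtonEnvironment
) -> tuple[np.ndarray, np.ndarray]:
    """Log-space weights of the closed and open tiers (overflow-safe)."""
    lxo = LN10 * (params.pK_o - env.pH_o)
    lxi = LN10 * (params.pK_i - env.pH_i)
    lE, lC, lD = math.log(params.E), math.log(params.C), math.log(params.D)
    lK = math.log(params.Kv0) + params.q_g * V / params.thermal_voltage
    log_closed = np.array([0.0, lxo, lxi, lE + lxo + lxi])
    log_open = lK + np.array([0.0, lC + lxo, lD + lxi, lC + lD + lE + lxo + lxi])
    return log_closed, log_open


def state_weights(
    params: AllostericParams, V: float, env: ProtonEnvironment
) -> StateWeights:
    """Weights of all eight states at membrane potential ``V`` (mV).

    May overflow to ``inf`` for extreme voltages; use
    :func:`open_probability` (log-space) when only the ratio is needed.
    """
    log_closed, log_open = _log_tier_weights(params, V, env)
    with np.errstate(over="ignore"):
        wc, wo = np.exp(log_closed), np.exp(log_open)
    return StateWeights(
        c=wc[0], c_ho=wc[1], c_hi=wc[2], c_hohi=wc[3],
        o=wo[0], o_ho=wo[1], o_hi=wo[2], o_hohi=wo[3],
    )


def open_probability(params, V, env: ProtonEnvironment):
    """Equilibrium open probability at membrane potential ``V`` (mV).

    Computed in log space as exp(logsumexp(open) - logsumexp(all)), so it
    is well behaved at arbitrarily large |V|.  Accepts a scalar or array
    of voltages.
    """
    V = np.asarray(V, dtype=float)
    scalar = V.ndim == 0
    Vs = np.atleast_1d(V)
    out = np.empty_like(Vs)
    for i, v in enumerate(Vs):
        log_closed, log_open = _log_tier_weights(params, float(v), env)
        lzo = logsumexp(log_open)
        lz = logsumexp(np.concatenate([log_closed, log_open]))
        out[i] = math.exp(lzo - lz)
    return float(out[0]) if scalar else out


def solve_v_half(params: AllostericParams, env: ProtonEnvironment) -> float:
    """Voltage (mV) at which the open probability is 1/2.

    Closed form: because only K(V) carries the voltage dependence,
    P(V) = 1/(1 + Zc/(K(V)*Zo')) with Zc, Zo' constant in V, so

        V_half = (V_T/q_g) * ln(Zc / (Kv0 * Zo'))

    with Zc = 1 + x_o + x_i + E*x_o*x_i and
    Zo' = 1 + C*x_o + D*x_i + C*D*E*x_o*x_i.
    """
    log_closed, log_open = _log_tier_weights(params, 0.0, env)
    # subtract log K(0) from the open tier to get log Zo'
    lzc = logsumexp(log_closed)
    lzo0 = logsumexp(log_open) - math.log(params.Kv0)
    return params.thermal_voltage / params.q_g * (lzc - lzo0 - math.log(params.Kv0))


def solve_v_threshold(
    params: AllostericParams,
    env: ProtonEnvironment,
    fraction: float = 0.1,
) -> float:
    """Voltage (mV) at which the open probability reaches ``fraction`` of
    its saturating value (which is 1), found numerically.

    The default 10% level is the conventional apparent activation
    threshold V_Thr.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie strictly in (0, 1), got {fraction}")
    if fraction == 0.5:
        return solve_v_half(params, env)

    def objective(v: float) -> float:
        return open_probability(params, v, env) - fraction

    # bracket around V_half, expanding until a sign change appears
    center = solve_v_half(params, env)
    half_width = 4.0 * abs(params.thermal_voltage / params.q_g)
    for _ in range(60):
        lo, hi = center - half_width, center + half_width
        if objective(lo) * objective(hi) < 0:
            return brentq(objective, lo, hi, xtol=1e-9)
        half_width *= 2.0
    raise RuntimeError("could not bracket the threshold voltage")


def v_half_vs_delta_ph(
    params: AllostericParams, ph_pairs: list[ProtonEnvironment]
) -> pd.DataFrame:
    """Model half-activation voltage for each pH condition.

    Returns a table with columns ``pH_o``, ``pH_i``, ``delta_pH``,
    ``V_half_mV``, one row per environment.  With the coral parameter set
    the curve is steeply decreasing in delta pH and saturates at both
    extremes because both proton sites titrate fully.
    """
    if len(ph_pairs) == 0:
        raise ValueError("ph_pairs must be non-empty")
    rows = [
        {
            "pH_o": env.pH_o,
            "pH_i": env.pH_i,
            "delta_pH": env.delta_ph,
            "V_half_mV": solve_v_half(params, env),
        }
        for env in ph_pairs
    ]
    return pd.DataFrame(rows)
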