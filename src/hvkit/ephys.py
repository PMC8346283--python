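"""Analysis of voltage-clamp proton-current recordings.

Covers the standard whole-cell / excised-patch workflow: P/4 leak
subtraction, extraction of conductance-voltage (G-V) relations assuming
ohmic instantaneous currents I = G*(V - V_rev), Boltzmann fits of the
G-V, the exponential foot used to define the apparent threshold voltage,
exponential-with-delay activation kinetics, the voltage dependence of
the kinetic parameters, and reversal potentials (Nernst prediction and
tail-current measurement).

Units: mV, ms, pA, nS, kelvin.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .constants import DEFAULT_TEMPERATURE_K, LN10, thermal_voltage_mv
from .gating import ProtonEnvironment

logger = logging.getLogger(__name__)

__all__ = [
    "VoltageProtocol",
    "CurrentFamily",
    "GVCurve",
    "BoltzmannFit",
    "ThresholdFit",
    "ActivationFit",
    "RateVoltageFit",
    "boltzmann_conductance",
    "nernst_potential",
    "reversal_from_tails",
    "conductance_from_iv",
    "fit_boltzmann",
    "fit_threshold",
    "fit_activation_trace",
    "fit_rate_voltage",
    "p4_leak_subtract",
]


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class VoltageProtocol:
    """A step-depolarization protocol.

    ``p4_subsweeps`` > 0 requests leak-estimation subsweeps of amplitude
    (V_test - holding)/N delivered from ``p4_holding_mV`` (a sub-threshold
    level at which the channel conductance is negligible).
    """

    holding_mV: float
    test_mV: tuple[float, ...]
    duration_ms: float
    dt_ms: float
    tail_mV: Optional[float] = None
    p4_subsweeps: int = 0
    p4_holding_mV: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dt_ms <= 0 or self.duration_ms <= 0:
            raise ValueError("sampling interval and duration must be positive")
        if len(set(self.test_mV)) != len(self.test_mV):
            raise ValueError("test potentials must be unique")
        object.__setattr__(self, "test_mV", tuple(float(v) for v in self.test_mV))

    def time_base(self) -> np.ndarray:
        return np.arange(0.0, self.duration_ms, self.dt_ms)


@dataclass
class CurrentFamily:
    """A family of current traces, one per test potential, on a shared
    time base, with the recording metadata needed downstream.

    Currents are holding-baseline-referenced (the steady current at the
    holding potential has been removed), the convention in which both
    channel and leak components scale with the voltage step.
    """

    protocol: VoltageProtocol
    time_ms: np.ndarray
    traces: dict[float, np.ndarray]
    metadata: dict = field(default_factory=dict)
    subsweeps: Optional[dict[float, list[np.ndarray]]] = None

    def __post_init__(self) -> None:
        lengths = {len(tr) for tr in self.traces.values()}
        if lengths and lengths != {len(self.time_ms)}:
            raise ValueError("all traces must share the time base length")
        if len(self.time_ms) > 1 and not np.all(np.diff(self.time_ms) > 0):
            raise ValueError("time base must be strictly increasing")

    @property
    def voltages(self) -> np.ndarray:
        return np.array(sorted(self.traces))

    @property
    def environment(self) -> ProtonEnvironment:
        return ProtonEnvironment(self.metadata["pH_o"], self.metadata["pH_i"])

    @property
    def temperature(self) -> float:
        return float(self.metadata.get("temperature_K", DEFAULT_TEMPERATURE_K))

    def steady_state_currents(self, last_fraction: float = 0.05) -> dict[float, float]:
        """Mean current over the trailing ``last_fraction`` of each pulse."""
        n = max(1, int(round(last_fraction * len(self.time_ms))))
        return {v: float(np.mean(tr[-n:])) for v, tr in self.traces.items()}


@dataclass
class GVCurve:
    """Conductance versus voltage, optionally normalized to G_max."""

    voltages_mV: np.ndarray
    conductance: np.ndarray
    sem: Optional[np.ndarray] = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.voltages_mV = np.asarray(self.voltages_mV, dtype=float)
        self.conductance = np.asarray(self.conductance, dtype=float)
        if self.voltages_mV.shape != self.conductance.shape:
            raise ValueError("voltage and conductance arrays differ in length")
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
            if self.sem.shape != self.conductance.shape:
                raise ValueError("sem array length mismatch")


@dataclass(frozen=True)
class BoltzmannFit:
    """Two-state Boltzmann description of a G-V curve."""

    V_half_mV: float
    q_e0: float
    G_max: float
    covariance: np.ndarray
    temperature_K: float

    @property
    def V_half_stderr(self) -> float:
        return float(np.sqrt(self.covariance[0, 0]))

    @property
    def q_stderr(self) -> float:
        return float(np.sqrt(self.covariance[1, 1]))

    def predict(self, V) -> np.ndarray:
        return boltzmann_conductance(
            np.asarray(V, float), self.V_half_mV, self.q_e0,
            self.G_max, self.temperature_K,
        )


@dataclass(frozen=True)
class ThresholdFit:
    """Exponential-foot fit of a G-V curve and the threshold it implies.

    The foot of the activation curve is fitted to G(V) = G' * exp(q*V/V_T)
    and V_Thr is the voltage at which that fit reaches ``fraction`` of
    G_max (10% by convention).
    """

    G_prime: float
    q_e0: float
    V_thr_mV: float
    fraction: float
    n_points: int


@dataclass(frozen=True)
class ActivationFit:
    """Exponential-with-delay fit of an activating current trace,
    I(t) = I_ss * (1 - exp(-(t - delta)/tau))."""

    I_ss_pA: float
    tau_ms: float
    delta_ms: float
    window_ms: tuple[float, float]
    residual_rms_pA: float
    covariance: np.ndarray


@dataclass(frozen=True)
class RateVoltageFit:
    """Exponential voltage dependence of a kinetic parameter,
    k(V) = k(0) * exp(-V * q_k / V_T)."""

    k0: float
    q_k_e0: float
    parameter: str
    covariance: np.ndarray


# ---------------------------------------------------------------------------
# reversal potentials


def nernst_potential(
    env: ProtonEnvironment, temperature: float = DEFAULT_TEMPERATURE_K
) -> float:
    """Proton equilibrium (reversal) potential in mV.

    E_rev = ln(10) * V_T * (pH_i - pH_o): -58.6 mV per unit of
    delta pH = pH_o - pH_i at 22 C.
    """
    return LN10 * thermal_voltage_mv(temperature) * (env.pH_i - env.pH_o)


def reversal_from_tails(voltages_mV, currents_pA) -> float:
    """Zero-crossing voltage of an instantaneous tail-current I-V, by
    linear interpolation between the two points bracketing the sign change.
    """
    v = np.asarray(voltages_mV, dtype=float)
    i = np.asarray(currents_pA, dtype=float)
    order = np.argsort(v)
    v, i = v[order], i[order]
    sign_change = np.nonzero(np.diff(np.signbit(i)))[0]
    if len(sign_change) == 0:
        exact = np.nonzero(i == 0)[0]
        if len(exact):
            return float(v[exact[0]])
        raise ValueError("tail currents do not change sign over the voltage range")
    k = sign_change[0]
    return float(v[k] - i[k] * (v[k + 1] - v[k]) / (i[k + 1] - i[k]))


# ---------------------------------------------------------------------------
# conductance extraction and G-V fitting


def conductance_from_iv(
    voltages_mV,
    currents_pA,
    V_rev_mV: float,
    guard_mV: float = 1.0,
    normalize: bool = False,
    sem_pA=None,
) -> GVCurve:
    """Chord conductance G(V) = I/(V - V_rev) in nS, assuming ohmic
    instantaneous currents.

    Voltages within ``guard_mV`` of the reversal potential are rejected
    (the division is ill-conditioned there).  ``normalize=True`` divides
    by the maximum conductance in the set; for incomplete saturation
    prefer normalizing by a fitted G_max (see :func:`fit_boltzmann`).
    """
    v = np.asarray(voltages_mV, dtype=float)
    i = np.asarray(currents_pA, dtype=float)
    driving = v - V_rev_mV
    if np.any(np.abs(driving) < guard_mV):
        bad = v[np.abs(driving) < guard_mV]
        raise ValueError(
            f"test potentials {bad} within {guard_mV} mV of V_rev={V_rev_mV} mV"
        )
    g = i / driving
    sem = None if sem_pA is None else np.asarray(sem_pA, float) / np.abs(driving)
    if normalize:
        gmax = float(np.max(g))
        if gmax <= 0:
            raise ValueError("cannot normalize: non-positive maximal conductance")
        g = g / gmax
        sem = None if sem is None else sem / gmax
    return GVCurve(v, g, sem=sem, normalized=normalize)


def boltzmann_conductance(V, V_half, q, G_max=1.0, temperature=DEFAULT_TEMPERATURE_K):
    """Boltzmann G-V: G(V) = G_max / (1 + exp(-q*(V - V_half)/V_T)).

    The exponent sign is chosen so conductance rises with depolarization
    (q > 0), the behavior of every proton-channel G-V.
    """
    vt = thermal_voltage_mv(temperature)
    return G_max / (1.0 + np.exp(-q * (np.asarray(V, float) - V_half) / vt))


def fit_boltzmann(
    gv: GVCurve, temperature: float = DEFAULT_TEMPERATURE_K
) -> BoltzmannFit:
    """Least-squares Boltzmann fit of a G-V curve.

    Normalized curves are fitted with G_max fixed at 1; raw curves fit
    G_max jointly.  Points are weighted by their sem when available.
    """
    v, g = gv.voltages_mV, gv.conductance
    if len(v) < 4:
        raise ValueError("need at least 4 points spanning the rise")
    if np.ptp(g) <= 0:
        raise ValueError("flat conductance data cannot constrain a Boltzmann fit")
    vt = thermal_voltage_mv(temperature)
    gmax0 = float(np.max(g))
    # crude midpoint/steepness seeds from the half-max crossing
    half = gmax0 / 2.0
    above = g >= half
    v0 = float(v[np.argmax(above)]) if above.any() else float(np.median(v))
    sigma = gv.sem if gv.sem is not None and np.all(gv.sem > 0) else None

    if gv.normalized:
        def model(V, V_half, q):
            return boltzmann_conductance(V, V_half, q, 1.0, temperature)

        p0 = [v0, 1.0]
    else:
        def model(V, V_half, q, G_max):
            return boltzmann_conductance(V, V_half, q, G_max, temperature)

        p0 = [v0, 1.0, gmax0]

    popt, pcov = curve_fit(model, v, g, p0=p0, sigma=sigma, maxfev=20000)
    if not np.all(np.isfinite(pcov)):
        raise RuntimeError("Boltzmann fit did not converge to a finite covariance")
    gmax = 1.0 if gv.normalized else float(popt[2])
    if popt[1] < 0:
        raise RuntimeError("fitted gating charge is negative; check data orientation")
    return BoltzmannFit(
        V_half_mV=float(popt[0]),
        q_e0=float(popt[1]),
        G_max=gmax,
        covariance=pcov,
        temperature_K=temperature,
    )


def fit_threshold(
    gv: GVCurve,
    fraction: float = 0.1,
    foot_cutoff: float = 0.3,
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> ThresholdFit:
    """Fit the exponential rise of the G-V foot, G = G'*exp(q*V/V_T),
    and locate the apparent threshold voltage.

    Only points with G/G_max <= ``foot_cutoff`` enter the fit (the
    exponential limit of the Boltzmann).  V_Thr solves
    G'*exp(q*V/V_T) = fraction*G_max, i.e.
    V_Thr = (V_T/q) * ln(fraction*G_max/G').
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    v, g = gv.voltages_mV, gv.conductance
    gmax = 1.0 if gv.normalized else float(np.max(g))
    mask = (g > 0) & (g <= foot_cutoff * gmax)
    if mask.sum() < 3:
        raise ValueError(
            f"only {int(mask.sum())} foot points below {foot_cutoff}*G_max; need >= 3"
        )
    vt = thermal_voltage_mv(temperature)
    # log-linear fit: ln G = ln G' + q V / V_T
    slope, intercept = np.polyfit(v[mask], np.log(g[mask]), 1)
    q = slope * vt
    g_prime = math.exp(intercept)
    if q <= 0:
        raise RuntimeError("foot of the G-V is not rising; cannot define a threshold")
    v_thr = vt / q * math.log(fraction * gmax / g_prime)
    return ThresholdFit(
        G_prime=g_prime, q_e0=q, V_thr_mV=v_thr,
        fraction=fraction, n_points=int(mask.sum()),
    )


# ---------------------------------------------------------------------------
# activation kinetics


def _activation_model(t, I_ss, tau, delta):
    return I_ss * (1.0 - np.exp(-(t - delta) / tau))


def fit_activation_trace(
    time_ms,
    current_pA,
    window_ms: Optional[tuple[float, float]] = None,
) -> ActivationFit:
    """Fit an activating trace to I(t) = I_ss*(1 - exp(-(t - delta)/tau)).

    ``window_ms`` restricts the fit; the default is the second half of
    the pulse, where the single-exponential form holds and the delay
    delta is an extrapolation of the late time course back to zero
    current.  The fitted window is recorded in the result.
    """
    t = np.asarray(time_ms, dtype=float)
    i = np.asarray(current_pA, dtype=float)
    if window_ms is None:
        window_ms = (t[0] + 0.5 * (t[-1] - t[0]), t[-1])
    lo, hi = window_ms
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9 or hi <= lo:
        raise ValueError(f"fit window {window_ms} outside trace span ({t[0]}, {t[-1]})")
    mask = (t >= lo) & (t <= hi)
    tw, iw = t[mask], i[mask]
    if len(tw) < 4:
        raise ValueError("fewer than 4 samples in the fit window")
    chunk = max(3, len(iw) // 10)
    i_end = float(np.mean(iw[-chunk:]))
    i_start = float(np.mean(iw[:chunk]))
    # reject clear decay; a flat (fully activated) window is acceptable,
    # though only I_ss is then identifiable
    if i_end <= 0 or i_start - i_end > 0.2 * abs(i_end):
        raise ValueError("trace is not rising toward a positive steady state")
    tau0 = max((hi - lo) / 3.0, 1e-3)
    p0 = [i_end, tau0, 0.0]
    popt, pcov = curve_fit(
        _activation_model, tw, iw, p0=p0,
        bounds=([0.0, 1e-9, 0.0], [np.inf, np.inf, np.inf]),
        maxfev=20000,
    )
    resid = iw - _activation_model(tw, *popt)
    return ActivationFit(
        I_ss_pA=float(popt[0]),
        tau_ms=float(popt[1]),
        delta_ms=float(popt[2]),
        window_ms=(float(lo), float(hi)),
        residual_rms_pA=float(np.sqrt(np.mean(resid**2))),
        covariance=pcov,
    )


def fit_rate_voltage(
    voltages_mV,
    k_ms,
    temperature: float = DEFAULT_TEMPERATURE_K,
    parameter: str = "tau",
    method: str = "log-linear",
) -> RateVoltageFit:
    """Fit the voltage dependence of a kinetic parameter to
    k(V) = k(0) * exp(-V*q_k/V_T).

    ``method='log-linear'`` (default) performs a linear regression on
    ln k, which is robust when k spans decades; ``method='direct'``
    minimizes squared error on k itself.
    """
    v = np.asarray(voltages_mV, dtype=float)
    k = np.asarray(k_ms, dtype=float)
    if len(v) < 3:
        raise ValueError("need at least 3 voltages")
    if np.any(k <= 0):
        raise ValueError("kinetic parameters must be positive")
    vt = thermal_voltage_mv(temperature)
    slope, intercept, cov = _polyfit_with_cov(v, np.log(k))
    k0, qk = math.exp(intercept), -slope * vt
    if method == "direct":
        def model(V, k0_, qk_):
            return k0_ * np.exp(-V * qk_ / vt)

        popt, cov = curve_fit(model, v, k, p0=[k0, qk], maxfev=20000)
        k0, qk = float(popt[0]), float(popt[1])
    elif method != "log-linear":
        raise ValueError(f"unknown method {method!r}")
    return RateVoltageFit(k0=k0, q_k_e0=qk, parameter=parameter, covariance=cov)


def _polyfit_with_cov(x, y):
    """Straight-line fit returning (slope, intercept, covariance);
    covariance is NaN when there are no residual degrees of freedom."""
    slope, intercept = np.polyfit(x, y, 1)
    dof = len(x) - 2
    if dof > 0:
        resid = y - (slope * x + intercept)
        s2 = float(resid @ resid) / dof
        X = np.column_stack([x, np.ones_like(x)])
        cov = s2 * np.linalg.inv(X.T @ X)
    else:
        cov = np.full((2, 2), np.nan)
    return float(slope), float(intercept), cov


# ---------------------------------------------------------------------------
# leak subtraction


def p4_leak_subtract(family: CurrentFamily) -> CurrentFamily:
    """P/N (default P/4) leak subtraction.

    Each test pulse of amplitude dV carries N subsweeps of amplitude
    dV/N delivered from a sub-threshold level, so the subsweep response
    is purely linear.  The corrected trace is raw - N * mean(subsweeps):
    a purely ohmic cell yields identically zero output, while channel
    current (absent at the subsweep level) is untouched.

    A single full-amplitude subsweep (N = 1 from the test level) would
    subtract channel current as well; N = 1 therefore triggers a warning.
    """
    if family.subsweeps is None:
        raise ValueError("family carries no P/4 subsweeps")
    n = family.protocol.p4_subsweeps
    if n < 1:
        raise ValueError("protocol declares no subsweeps")
    if n == 1:
        warnings.warn(
            "P/1 subtraction removes channel current along with the leak",
            UserWarning,
            stacklevel=2,
        )
    corrected = {}
    for v, trace in family.traces.items():
        if v not in family.subsweeps or len(family.subsweeps[v]) != n:
            raise ValueError(f"missing subsweeps for test potential {v} mV")
        sub = np.mean(np.stack(family.subsweeps[v]), axis=0)
        corrected[v] = trace - n * sub
    logger.info("P/%d leak subtraction applied to %d traces", n, len(corrected))
    return CurrentFamily(
        protocol=family.protocol,
        time_ms=family.time_ms.copy(),
        traces=corrected,
        metadata={**family.metadata, "leak_subtracted": True},
        subsweeps=None,
    )
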