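"""Zinc inhibition analysis: voltage-dependent (Woodhull) block and the
Hill dose-response.

Extracellular Zn2+ blocks proton channels by binding within the membrane
electric field.  The Woodhull formalism places the binding site at a
fraction ``delta`` of the field measured from the outside, so for a
blocker of valence ``z`` the blocked fraction follows a Boltzmann in
voltage with slope charge delta*z.  Concentration dependence is captured
empirically by a Hill curve with apparent dissociation constant K_D and
coefficient n_H.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .constants import DEFAULT_TEMPERATURE_K, thermal_voltage_mv

__all__ = [
    "BlockFit",
    "fraction_blocked",
    "woodhull_fraction",
    "fit_woodhull",
    "hill_fraction",
    "fit_hill",
]


@dataclass(frozen=True)
class BlockFit:
    """Fitted blocker parameters; Woodhull and Hill fields are populated
    by their respective fitting routines."""

    woodhull_delta: Optional[float] = None
    z: Optional[float] = None
    V_half_block_mV: Optional[float] = None
    hill_KD_uM: Optional[float] = None
    hill_n: Optional[float] = None
    covariance: Optional[np.ndarray] = None


def fraction_blocked(I_control, I_blocker, clip: bool = False):
    """Blocked fraction F_B = 1 - I_blocker/I_control.

    Values outside [0, 1] (possible with noisy records) are kept by
    default so fits remain unbiased; ``clip=True`` clips for reporting
    and warns when clipping occurred.
    """
    ic = np.asarray(I_control, dtype=float)
    ib = np.asarray(I_blocker, dtype=float)
    if np.any(ic == 0):
        raise ValueError("control current is zero; blocked fraction undefined")
    fb = 1.0 - ib / ic
    if clip:
        if np.any((fb < 0) | (fb > 1)):
            warnings.warn(
                "blocked fractions outside [0, 1] clipped for reporting",
                UserWarning,
                stacklevel=2,
            )
        fb = np.clip(fb, 0.0, 1.0)
    return float(fb) if fb.ndim == 0 else fb


def woodhull_fraction(
    V,
    delta: float,
    z: float,
    V_half: float,
    temperature: float = DEFAULT_TEMPERATURE_K,
):
    """Woodhull blocked fraction
    F_B(V) = 1/(1 + exp(-delta*z*(V - V_half)/V_T)).

    ``delta`` is the electrical distance of the binding site from the
    extracellular face; block deepens with depolarization for
    delta*z > 0.
    """
    vt = thermal_voltage_mv(temperature)
    with np.errstate(over="ignore"):  # exp overflow saturates F_B at 0
        return 1.0 / (1.0 + np.exp(-delta * z * (np.asarray(V, float) - V_half) / vt))


def fit_woodhull(
    voltages_mV,
    blocked_fraction,
    z: float = 2.0,
    temperature: float = DEFAULT_TEMPERATURE_K,
    free_z: bool = False,
) -> BlockFit:
    """Least-squares Woodhull fit of blocked fraction versus voltage.

    The blocker valence ``z`` is held fixed (default 2 for Zn2+);
    ``free_z=True`` fits it jointly with delta, at the cost of a strong
    delta-z correlation (only their product is well determined).
    """
    v = np.asarray(voltages_mV, dtype=float)
    fb = np.asarray(blocked_fraction, dtype=float)
    if len(v) < 4:
        raise ValueError("need at least 4 voltages")
    v0 = float(v[np.argmin(np.abs(fb - 0.5))])
    if free_z:
        def model(V, delta, V_half, z_):
            return woodhull_fraction(V, delta, z_, V_half, temperature)

        popt, pcov = curve_fit(model, v, fb, p0=[0.2, v0, z], maxfev=20000)
        delta, v_half, z_fit = (float(x) for x in popt)
    else:
        def model(V, delta, V_half):
            return woodhull_fraction(V, delta, z, V_half, temperature)

        popt, pcov = curve_fit(model, v, fb, p0=[0.2, v0], maxfev=20000)
        delta, v_half, z_fit = float(popt[0]), float(popt[1]), z
    return BlockFit(
        woodhull_delta=delta, z=z_fit, V_half_block_mV=v_half, covariance=pcov
    )


def hill_fraction(conc_uM, KD_uM: float, n: float):
    """Hill blocked fraction F_B = 1/(1 + (K_D/[blocker])^n)."""
    c = np.asarray(conc_uM, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentration must be positive")
    return 1.0 / (1.0 + (KD_uM / c) ** n)


def fit_hill(conc_uM, blocked_fraction) -> BlockFit:
    """Least-squares Hill fit of a dose-response table.

    Concentrations should span at least a couple of decades to constrain
    both K_D and n_H; the fit runs on linear F_B (no weighting).
    """
    c = np.asarray(conc_uM, dtype=float)
    fb = np.asarray(blocked_fraction, dtype=float)
    if len(np.unique(c)) < 2:
        raise ValueError("dose-response needs more than one concentration")
    if len(c) < 4:
        raise ValueError("need at least 4 concentrations")
    # seed K_D near the half-block concentration on a log axis
    kd0 = float(c[np.argmin(np.abs(fb - 0.5))])
    popt, pcov = curve_fit(
        hill_fraction, c, fb, p0=[kd0, 1.0],
        bounds=([1e-12, 1e-3], [np.inf, 100.0]), maxfev=20000,
    )
    return BlockFit(hill_KD_uM=float(popt[0]), hill_n=float(popt[1]), covariance=pcov)
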