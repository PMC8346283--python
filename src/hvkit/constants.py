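"""Physical constants and unit helpers.

Units used throughout the package: membrane potential in mV, time in ms,
current in pA, conductance in nS (so that nS * mV = pA), temperature in
kelvin, charge in elementary charges (e0), concentration in uM.
"""

from scipy import constants as _const

#: Default recording temperature, kelvin (22 degrees C).
DEFAULT_TEMPERATURE_K: float = 295.15

LN10 = 2.302585092994046


def thermal_voltage_mv(temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """Thermal voltage k_B*T/e0 in millivolts.

    At 22 C (295.15 K) this is ~25.434 mV; it sets the voltage scale of
    every exponential voltage dependence in the package (gating charge q
    enters as exp(q*V/V_T)).
    """
    if temperature_k <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_k}")
    return 1e3 * _const.k * temperature_k / _const.e
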