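import math

import numpy as np
import pytest

from hvkit.constants import thermal_voltage_mv
from hvkit.gating import AMHV1_SCHEME_I, AllostericParams, ProtonEnvironment


@pytest.fixture
def coral_params() -> AllostericParams:
    """The coral-channel allosteric parameter set."""
    return AMHV1_SCHEME_I


@pytest.fixture
def ph_7_6() -> ProtonEnvironment:
    return ProtonEnvironment(pH_o=7.0, pH_i=6.0)


def enumerate_states(params: AllostericParams, V: float, env: ProtonEnvironment):
    """Independent brute-force enumeration of the eight state weights.

    Deliberately written with plain scalar arithmetic (no log-space
    tricks, no shared code path with the package) so it can serve as an
    oracle for the partition-function implementation.
    """
    x_o = 10.0 ** (params.pK_o - env.pH_o)
    x_i = 10.0 ** (params.pK_i - env.pH_i)
    K = params.Kv0 * math.exp(params.q_g * V / thermal_voltage_mv(params.temperature))
    closed = [1.0, x_o, x_i, params.E * x_o * x_i]
    open_ = [
        K,
        K * params.C * x_o,
        K * params.D * x_i,
        K * params.C * params.D * params.E * x_o * x_i,
    ]
    return closed, open_


def brute_force_popen(params: AllostericParams, V: float, env: ProtonEnvironment):
    closed, open_ = enumerate_states(params, V, env)
    return sum(open_) / (sum(closed) + sum(open_))
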