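"""Tests of the eight-state allosteric gating model.

Derived expectations were computed with the brute-force state
enumeration in conftest (an independent oracle using plain scalar
arithmetic) before being frozen here.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hvkit.constants import thermal_voltage_mv
from hvkit.gating import (
    AMHV1_SCHEME_I,
    AllostericParams,
    ProtonEnvironment,
    binding_weight,
    open_probability,
    solve_v_half,
    solve_v_threshold,
    state_weights,
    v_half_vs_delta_ph,
)

from conftest import brute_force_popen, enumerate_states

VT = thermal_voltage_mv(295.15)


# ---------------------------------------------------------------------------
# binding weight


@pytest.mark.parametrize(
    "pK, pH, expected",
    [
        (7.0, 7.0, 1.0),               # half-protonated at pH = pK
        (3.4, 7.0, 10.0 ** (-3.6)),    # acidic external site at neutral pH
        (7.0, 6.0, 10.0),              # one unit below pK: tenfold bound
    ],
)
def test_binding_weight_powers_of_ten(pK, pH, expected):
    assert binding_weight(pK, pH) == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------------
# state weights and open probability


def test_state_weights_partition_sums_neutral_ph(coral_params):
    """Frozen oracle values: V=0, pH 7/7 gives closed tier 127.5946 and
    open tier 5.1256 (weights relative to the unliganded closed state)."""
    w = state_weights(coral_params, 0.0, ProtonEnvironment(7.0, 7.0))
    zc, zo = w.partition()
    assert w.c == 1.0
    assert zc == pytest.approx(127.59457276412212, rel=1e-9)
    assert zo == pytest.approx(5.12564432157799, rel=1e-9)
    assert w.open_probability() == pytest.approx(0.03861992117047442, rel=1e-9)


def test_neutral_couplings_make_tiers_proportional():
    """With C=D=E=1 the protonation factors of the two tiers are
    identical, so P_open loses all pH dependence."""
    params = AllostericParams(Kv0=1e-3, q_g=1.0, C=1.0, D=1.0, E=1.0, pK_o=5.0, pK_i=7.0)
    w = state_weights(params, 20.0, ProtonEnvironment(6.0, 6.5))
    np.testing.assert_allclose(w.open() / w.closed(), w.o, rtol=1e-12)
    p_ref = open_probability(params, 20.0, ProtonEnvironment(7.0, 7.0))
    for env in [ProtonEnvironment(4.0, 9.0), ProtonEnvironment(9.0, 4.0)]:
        assert open_probability(params, 20.0, env) == pytest.approx(p_ref, rel=1e-12)


def test_alkaline_limit_reduces_to_two_states(coral_params):
    """At pH far above both pKs only the unliganded C and O states carry
    weight (pH must exceed pK_i by more than log10(D) for the open tier,
    since D amplifies internal-site occupancy there)."""
    w = state_weights(coral_params, 0.0, ProtonEnvironment(20.0, 20.0))
    zc, zo = w.partition()
    assert zc == pytest.approx(w.c, rel=1e-4)
    assert zo == pytest.approx(w.o, rel=1e-4)


def test_open_probability_matches_brute_force_enumeration():
    """Oracle equivalence over 1000 random parameter/voltage/pH draws
    (rel. tol. 1e-12)."""
    rng = np.random.default_rng(20260920)
    for _ in range(1000):
        params = AllostericParams(
            Kv0=10.0 ** rng.uniform(-6, 0),
            q_g=rng.uniform(0.3, 3.0),
            C=10.0 ** rng.uniform(-4, 4),
            D=10.0 ** rng.uniform(-4, 4),
            E=10.0 ** rng.uniform(-4, 4),
            pK_o=rng.uniform(2, 9),
            pK_i=rng.uniform(2, 9),
        )
        env = ProtonEnvironment(rng.uniform(4, 9), rng.uniform(4, 9))
        V = rng.uniform(-150, 150)
        assert open_probability(params, V, env) == pytest.approx(
            brute_force_popen(params, V, env), rel=1e-12
        )


def test_open_probability_limits_and_monotonicity(coral_params, ph_7_6):
    assert open_probability(coral_params, 2000.0, ph_7_6) == pytest.approx(1.0, abs=1e-9)
    assert open_probability(coral_params, -2000.0, ph_7_6) == pytest.approx(0.0, abs=1e-9)
    V = np.linspace(-200, 300, 201)
    p = open_probability(coral_params, V, ph_7_6)
    assert np.all(np.diff(p) > 0)
    assert np.all((p > 0) & (p < 1))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    v=st.floats(-300, 300),
    pho=st.floats(3, 10),
    phi=st.floats(3, 10),
)
def test_detailed_balance_every_cycle(v, pho, phi):
    """The product of equilibrium ratios around each 4-cycle of the
    state graph is 1: weights are state functions by construction."""
    params = AMHV1_SCHEME_I
    env = ProtonEnvironment(pho, phi)
    closed, open_ = enumerate_states(params, v, env)
    c, c_ho, c_hi, c_hohi = closed
    o, o_ho, o_hi, o_hohi = open_
    # closed tier protonation square, open tier square, and the two
    # conformational squares per site
    for loop in [
        (c / c_ho) * (c_ho / c_hohi) * (c_hohi / c_hi) * (c_hi / c),
        (o / o_ho) * (o_ho / o_hohi) * (o_hohi / o_hi) * (o_hi / o),
        (c / o) * (o / o_ho) * (o_ho / c_ho) * (c_ho / c),
        (c / o) * (o / o_hi) * (o_hi / c_hi) * (c_hi / c),
    ]:
        assert loop == pytest.approx(1.0, rel=1e-9)


# ---------------------------------------------------------------------------
# half-activation voltage


def test_v_half_two_state_limit():
    """With both sites unprotonatable the midpoint is
    (V_T/q_g)*ln(1/Kv0): 251.89 mV for Kv0 = 5e-5 (frozen from the
    closed form evaluated independently)."""
    params = AllostericParams(
        Kv0=5e-5, q_g=1.0, C=1.0, D=1.0, E=1.0, pK_o=-20.0, pK_i=-20.0
    )
    env = ProtonEnvironment(7.0, 7.0)  # x_o = x_i ~ 1e-27
    assert solve_v_half(params, env) == pytest.approx(251.88588793729195, rel=1e-9)


def test_v_half_coral_prediction(coral_params, ph_7_6):
    """Frozen closed-form value for the coral set at pH_o 7 / pH_i 6."""
    assert solve_v_half(coral_params, ph_7_6) == pytest.approx(81.58050785612389, rel=1e-9)


def test_v_half_agrees_with_numeric_root(coral_params):
    """Closed form vs direct root of P(V) - 1/2, to 1e-6 mV."""
    from scipy.optimize import brentq

    for env in [ProtonEnvironment(7.0, p) for p in (4.0, 6.0, 7.5, 9.0, 11.0)]:
        vh = solve_v_half(coral_params, env)
        root = brentq(
            lambda v: open_probability(coral_params, v, env) - 0.5,
            vh - 50.0, vh + 50.0, xtol=1e-9,
        )
        assert vh == pytest.approx(root, abs=1e-6)
        assert open_probability(coral_params, vh, env) == pytest.approx(0.5, abs=1e-12)


def test_v_half_kv0_doubling_shift(coral_params):
    """Doubling Kv0 shifts V_half by exactly -V_T*ln(2)/q_g at any pH."""
    import dataclasses

    doubled = dataclasses.replace(coral_params, Kv0=2 * coral_params.Kv0)
    shift = -VT * math.log(2.0) / coral_params.q_g
    for env in [ProtonEnvironment(7.0, p) for p in (5.0, 7.0, 9.0)]:
        assert solve_v_half(doubled, env) - solve_v_half(coral_params, env) == pytest.approx(
            shift, rel=1e-9
        )


# ---------------------------------------------------------------------------
# threshold voltage


def test_threshold_at_half_equals_v_half(coral_params, ph_7_6):
    assert solve_v_threshold(coral_params, ph_7_6, fraction=0.5) == pytest.approx(
        solve_v_half(coral_params, ph_7_6), abs=1e-6
    )


def test_threshold_below_v_half_and_monotone(coral_params, ph_7_6):
    v10 = solve_v_threshold(coral_params, ph_7_6, fraction=0.1)
    v30 = solve_v_threshold(coral_params, ph_7_6, fraction=0.3)
    vh = solve_v_half(coral_params, ph_7_6)
    assert v10 < v30 < vh
    assert open_probability(coral_params, v10, ph_7_6) == pytest.approx(0.1, abs=1e-8)


@pytest.mark.parametrize("fraction", [0.0, 1.0, 1.5, -0.1])
def test_threshold_rejects_degenerate_fraction(coral_params, ph_7_6, fraction):
    with pytest.raises(ValueError):
        solve_v_threshold(coral_params, ph_7_6, fraction=fraction)


# ---------------------------------------------------------------------------
# V_half vs delta pH curve


def test_vhalf_sweep_monotone_decreasing_with_plateaus(coral_params):
    """The predicted V_half falls monotonically with delta pH and
    saturates at both extremes; the plateaus agree with the closed-form
    asymptotes in which one proton site is empty or full."""
    phis = np.arange(-2.0, 16.01, 0.1)
    envs = [ProtonEnvironment(7.0, p) for p in phis]
    table = v_half_vs_delta_ph(coral_params, envs)
    table = table.sort_values("delta_pH", ignore_index=True)
    assert np.all(np.diff(table["V_half_mV"]) <= 1e-9)

    x_o = 10.0 ** (coral_params.pK_o - 7.0)
    # x_i -> inf: internal site saturated in both tiers
    acid = VT * math.log(
        (1 + coral_params.E * x_o)
        / (coral_params.Kv0 * coral_params.D * (1 + coral_params.C * coral_params.E * x_o))
    )
    # x_i -> 0: internal site empty
    alkaline = VT * math.log((1 + x_o) / (coral_params.Kv0 * (1 + coral_params.C * x_o)))
    assert table["V_half_mV"].iloc[-1] == pytest.approx(acid, abs=1.0)
    assert table["V_half_mV"].iloc[0] == pytest.approx(alkaline, abs=1.0)


def test_vhalf_sweep_slope_exceeds_40mV_per_unit(coral_params):
    """The steep limb of the curve is steeper than the canonical
    40 mV per delta-pH unit."""
    phis = np.arange(3.0, 16.01, 0.05)
    envs = [ProtonEnvironment(7.0, p) for p in phis]
    table = v_half_vs_delta_ph(coral_params, envs).sort_values(
        "delta_pH", ignore_index=True
    )
    slope = np.gradient(table["V_half_mV"].to_numpy(), table["delta_pH"].to_numpy())
    assert np.max(np.abs(slope)) > 40.0


def test_vhalf_flat_with_neutral_couplings():
    params = AllostericParams(
        Kv0=5e-5, q_g=1.0, C=1.0, D=1.0, E=1.0, pK_o=3.4, pK_i=7.0
    )
    envs = [ProtonEnvironment(7.0, p) for p in np.arange(3.0, 11.0, 0.5)]
    table = v_half_vs_delta_ph(params, envs)
    assert np.ptp(table["V_half_mV"].to_numpy()) < 1e-9


def test_vhalf_sweep_rejects_empty_input(coral_params):
    with pytest.raises(ValueError):
        v_half_vs_delta_ph(coral_params, [])


# ---------------------------------------------------------------------------
# parameter validation and serialization


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(Kv0=-1.0), dict(Kv0=0.0), dict(C=0.0), dict(D=-2.0),
        dict(E=0.0), dict(q_g=0.0), dict(temperature=0.0),
    ],
)
def test_invalid_params_rejected(kwargs):
    base = dict(Kv0=5e-5, q_g=1.0, C=2e-4, D=1e5, E=5e5, pK_o=3.4, pK_i=7.0)
    base.update(kwargs)
    with pytest.raises(ValueError):
        AllostericParams(**base)


def test_params_config_round_trip(coral_params):
    d = coral_params.to_dict()
    assert set(d) == {"Kv0", "q_g", "C", "D", "E", "pK_o", "pK_i", "temperature_K"}
    assert AllostericParams.from_dict(d) == coral_params
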