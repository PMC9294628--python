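"""Channel kinetics, membrane current and synapse unit tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pyramidal.errors import InvalidInputError, InvalidStateError
from pyramidal.model_core import (
    GatingState,
    HHChannelParameters,
    SynapseParameters,
    advance_gate,
    gating_equilibrium,
    rate_constants,
    somatic_membrane_current,
    synaptic_current,
    synaptic_release_probability,
)

from conftest import rk4_gate_trajectory


class TestRateConstants:
    @pytest.mark.parametrize(
        "v,attr,expected",
        [
            (-65.0, "beta_n", 0.125),          # exp(0)
            (-65.0, "alpha_h", 0.07),          # exp(0)
            (-55.0, "alpha_n", 0.1),           # removable singularity limit
            (-40.0, "alpha_m", 1.0),           # removable singularity limit
            (-35.0, "beta_h", 0.5),            # logistic midpoint
        ],
    )
    def test_known_values(self, v, attr, expected):
        assert getattr(rate_constants(v), attr) == pytest.approx(expected, abs=1e-12)

    def test_continuity_across_singularities(self):
        for v0, attr in ((-55.0, "alpha_n"), (-40.0, "alpha_m")):
            lim = getattr(rate_constants(v0), attr)
            for eps in (1e-6, -1e-6):
                assert abs(getattr(rate_constants(v0 + eps), attr) - lim) < 1e-5

    def test_rates_positive_and_finite_over_domain(self):
        for v in np.linspace(-100, 100, 401):
            r = rate_constants(float(v))
            for f in (r.alpha_n, r.beta_n, r.alpha_m, r.beta_m, r.alpha_h, r.beta_h):
                assert math.isfinite(f) and f >= 0

    def test_nonfinite_voltage_rejected(self):
        with pytest.raises(InvalidInputError):
            rate_constants(float("nan"))
        with pytest.raises(InvalidInputError):
            rate_constants(float("inf"))


class TestGatingEquilibrium:
    def test_values_at_rest(self):
        # frozen from direct evaluation of the rate functions at -65 mV
        eq = gating_equilibrium(-65.0)
        assert eq.n_inf == pytest.approx(0.317676914061, abs=1e-9)
        assert eq.tau_n == pytest.approx(5.45858468751, abs=1e-8)

    def test_ranges(self):
        for v in np.linspace(-100, 100, 101):
            eq = gating_equilibrium(float(v))
            for g in ("n", "m", "h"):
                assert 0.0 < getattr(eq, f"{g}_inf") < 1.0
                assert getattr(eq, f"tau_{g}") > 0.0


class TestAdvanceGate:
    def test_fixed_point_of_dynamics(self):
        eq = gating_equilibrium(-50.0)
        assert advance_gate(eq.n_inf, -50.0, 0.1, "n") == pytest.approx(
            eq.n_inf, abs=1e-15
        )

    def test_tiny_dt_returns_input(self):
        assert advance_gate(0.4, -60.0, 1e-12, "m") == pytest.approx(0.4, abs=1e-9)

    def test_against_rk4_oracle_single_step(self):
        # x=0.2, V=-40, one 0.1 ms step vs RK4 at dt=1e-4
        ours = advance_gate(0.2, -40.0, 0.1, "n")
        oracle = rk4_gate_trajectory("n", 0.2, -40.0, 1e-4, 0.1)[-1]
        assert ours == pytest.approx(oracle, abs=1e-6)

    @pytest.mark.parametrize("gate", ["n", "m", "h"])
    def test_trajectory_against_rk4_oracle(self, gate):
        # 50 ms at fixed voltage, coarse exponential steps vs fine RK4
        v, dt = -40.0, 0.1
        x = 0.2
        oracle = rk4_gate_trajectory(gate, 0.2, v, 1e-4, 50.0)
        for k in range(500):
            x = advance_gate(x, v, dt, gate)
            ref = oracle[int(round((k + 1) * dt / 1e-4))]
            assert abs(x - ref) < 1e-4

    def test_invalid_gate_value_rejected(self):
        with pytest.raises(InvalidStateError):
            advance_gate(1.2, -60.0, 0.1, "n")

    @given(
        x=st.floats(0.0, 1.0),
        v=st.floats(-100.0, 100.0),
        dt=st.floats(1e-3, 10.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_gate_closure_and_betweenness(self, x, v, dt):
        out = advance_gate(x, v, dt, "m")
        x_inf = gating_equilibrium(v).m_inf
        assert 0.0 <= out <= 1.0
        lo, hi = sorted((x, x_inf))
        assert lo - 1e-12 <= out <= hi + 1e-12

    def test_iteration_converges_to_equilibrium(self):
        v = -30.0
        eq = gating_equilibrium(v)
        x = 0.01
        for _ in range(2000):
            x = advance_gate(x, v, 1.0, "h")
        assert abs(x - eq.h_inf) < 1e-9


class TestSomaticMembraneCurrent:
    def test_zero_at_leak_reversal_with_closed_gates(self):
        p = HHChannelParameters()
        assert somatic_membrane_current(p.e_leak, GatingState(0, 0, 0), p) == 0.0

    def test_sodium_term_vanishes_at_sodium_reversal(self):
        p = HHChannelParameters()
        i = somatic_membrane_current(p.e_na, GatingState(m=1, h=1, n=0), p)
        assert i == pytest.approx(p.g_leak_ms * (p.e_na - p.e_leak), rel=1e-12)

    def test_value_at_rest_equilibrium(self):
        # frozen from independent evaluation of the current sum at -65 mV
        p = HHChannelParameters()
        from pyramidal.model_core import gating_equilibrium

        eq = gating_equilibrium(-65.0)
        i = somatic_membrane_current(
            -65.0, GatingState(m=eq.m_inf, h=eq.h_inf, n=eq.n_inf), p
        )
        assert i == pytest.approx(-0.0303237091825, abs=1e-9)

    def test_parameter_invariants_enforced(self):
        with pytest.raises(InvalidInputError):
            HHChannelParameters(g_na=-1.0)
        with pytest.raises(InvalidInputError):
            HHChannelParameters(c_m=0.0)
        with pytest.raises(InvalidInputError):
            HHChannelParameters(e_na=-80.0)  # below E_K


class TestSynapse:
    def test_release_probability(self):
        p = SynapseParameters()
        assert synaptic_release_probability(0.0, p) == 1.0
        assert synaptic_release_probability(p.tau_s, p) == pytest.approx(math.exp(-1))
        assert synaptic_release_probability(1e6, p) == pytest.approx(0.0, abs=1e-12)
        assert synaptic_release_probability(None, p) == 0.0

    def test_negative_time_rejected(self):
        with pytest.raises(InvalidInputError):
            synaptic_release_probability(-1.0, SynapseParameters())

    def test_current(self):
        p = SynapseParameters()
        assert synaptic_current(p.e_syn, 0.0, p) == 0.0
        assert synaptic_current(-65.0, None, p) == 0.0
        assert synaptic_current(-65.0, 0.0, p) == pytest.approx(0.05 * (-65.0))

    def test_parameter_invariants(self):
        with pytest.raises(InvalidInputError):
            SynapseParameters(p_max=1.5)
        with pytest.raises(InvalidInputError):
            SynapseParameters(tau_s=0.0)
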