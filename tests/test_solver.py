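"""Backward-Euler stepping: equilibrium, firing regimes, coupling,
stability, determinism and spike detection."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from pyramidal.errors import ConfigurationError
from pyramidal.model_core import GatingState, HHChannelParameters, gating_equilibrium, somatic_membrane_current
from pyramidal.solver import (
    CompartmentState,
    GeometryParameters,
    NeuronParameters,
    StimulusProtocol,
    Waveform,
    detect_spikes,
    initial_state,
    run_protocol,
    step_single,
)
from pyramidal.validation import constant_current_protocol


def spikes_after(result, t0=100.0):
    sp = result.soma_spikes
    return sp[sp >= t0]


class TestStepSingle:
    def test_rest_equilibrium_is_invariant(self):
        # locate the true resting voltage by root finding on the stationary
        # membrane current, then check a zero-input step leaves it in place
        p = HHChannelParameters()

        def stationary_current(v):
            eq = gating_equilibrium(v)
            g = GatingState(m=eq.m_inf, h=eq.h_inf, n=eq.n_inf)
            return somatic_membrane_current(v, g, p)

        v_rest = brentq(stationary_current, -75.0, -55.0, xtol=1e-13)
        eq = gating_equilibrium(v_rest)
        state = CompartmentState(
            v=v_rest, gates=GatingState(m=eq.m_inf, h=eq.h_inf, n=eq.n_inf)
        )
        out = step_single(state, 0.0, 0.1)
        assert abs(out.v - v_rest) < 1e-9

    def test_passive_step_matches_closed_form_implicit_solution(self):
        # all active conductances zeroed: the step must equal the analytic
        # solution of the implicit (backward-Euler) RC update
        hh = HHChannelParameters(g_na=0.0, g_k=0.0)
        geo = GeometryParameters()
        v0 = -70.0
        state = CompartmentState(v=v0, gates=GatingState(0.0, 0.0, 0.0))
        out = step_single(state, 0.5, 0.1, p=hh, geom=geo)
        dens = 0.1 * 0.5 / geo.a_soma
        gl = hh.g_leak_ms
        cmdt = hh.c_m / 0.1
        expected = (cmdt * v0 + gl * hh.e_leak + dens) / (cmdt + gl)
        assert abs(out.v - expected) < 1e-9


class TestFiringRegimes:
    def test_small_step_elicits_exactly_one_spike(self):
        r = run_protocol("single", None, constant_current_protocol(0.3))
        assert len(spikes_after(r)) == 1

    def test_large_step_elicits_repetitive_firing(self):
        r = run_protocol("single", None, constant_current_protocol(3.0))
        assert len(spikes_after(r)) >= 5

    def test_early_spike_times_converge_under_dt_refinement(self):
        # the implicit scheme is first order, so the period carries an O(dt)
        # bias and spike-time differences grow linearly with spike index;
        # the first spikes of the halved-step solution stay within two
        # coarse steps and the per-spike drift is a small fraction of the ISI
        s = {}
        for dt in (0.1, 0.05):
            proto = constant_current_protocol(3.0, stim_duration=300.0, dt=dt)
            r = run_protocol("single", None, proto)
            s[dt] = spikes_after(r)[:3]
        diffs = np.abs(s[0.1] - s[0.05])
        assert diffs[0] <= 0.2
        drift_per_spike = np.diff(diffs).max()
        isi = np.diff(s[0.1]).mean()
        assert drift_per_spike < 0.05 * isi


class TestStability:
    @pytest.mark.parametrize("i_nA", [0.0, 5.0, 10.0])
    def test_bounded_voltages_at_coarse_dt(self, i_nA):
        proto = constant_current_protocol(i_nA, stim_duration=500.0, dt=1.0)
        r = run_protocol("single", None, proto)
        assert r.v_soma.min() >= -120.0 and r.v_soma.max() <= 80.0


class TestTwoCompartment:
    def test_decoupled_soma_equals_single_model_bitwise(self):
        geo = GeometryParameters(g_ds=0.0, g_sd=0.0)
        params = NeuronParameters(geometry=geo)
        proto = constant_current_protocol(3.0, stim_duration=500.0)
        r2 = run_protocol("two", params, proto)
        r1 = run_protocol("single", params, proto)
        assert np.array_equal(r2.v_soma, r1.v_soma)

    def test_decoupled_dendrite_follows_its_own_rc_solution(self):
        geo = GeometryParameters(g_ds=0.0, g_sd=0.0)
        params = NeuronParameters(geometry=geo)
        proto = StimulusProtocol(duration=50.0)
        r = run_protocol("two", params, proto)
        # explicit recurrence of the uncoupled passive dendrite
        hh = params.hh
        cmdt = hh.c_m / proto.dt
        v = -65.0
        for k in range(proto.n_steps):
            v = (cmdt * v + hh.g_leak_ms * hh.e_leak) / (cmdt + hh.g_leak_ms)
            assert r.v_dend[k + 1] == v

    def test_equal_voltages_make_coupling_invisible(self):
        # both compartments passive and at the same potential: coupling
        # terms exchange zero current, so the dendrite evolves as if uncoupled
        hh = HHChannelParameters(g_na=0.0, g_k=0.0)
        for g in (0.0, 0.5):
            params = NeuronParameters(
                hh=hh, geometry=GeometryParameters(g_ds=g, g_sd=g)
            )
            r = run_protocol("two", params, StimulusProtocol(duration=20.0))
            if g == 0.0:
                ref = r.v_dend.copy()
            else:
                assert np.allclose(r.v_dend, ref, atol=1e-9)
                assert np.allclose(r.v_soma, r.v_dend, atol=1e-9)

    def test_dendritic_drive_fires_dendrite_then_soma(self):
        r = run_protocol("two", None, constant_current_protocol(3.0, "dend"))
        assert len(r.dcaap_onsets) >= 5
        assert len(r.soma_spikes) >= 1
        assert r.dcaap_onsets[0] < r.soma_spikes[0]

    def test_somatic_drive_never_triggers_dendrite(self):
        r = run_protocol("two", None, constant_current_protocol(10.0, "soma"))
        assert len(spikes_after(r)) >= 1
        assert len(r.dcaap_onsets) == 0
        assert r.v_dend.max() < -36.0

    def test_dcaap_intervals_regular_under_constant_drive(self):
        r = run_protocol("two", None, constant_current_protocol(3.0, "dend"))
        iv = np.diff(r.dcaap_onsets)
        assert np.all(np.abs(iv - iv[0]) <= 0.1 + 1e-9)

    def test_somatic_frequency_nondecreasing_in_somatic_current(self):
        counts = []
        for i_nA in (1.0, 2.0, 3.0, 4.0, 5.0):
            r = run_protocol(
                "two", None, constant_current_protocol(i_nA, stim_duration=1000.0)
            )
            counts.append(len(spikes_after(r)))
        assert all(b >= a for a, b in zip(counts, counts[1:]))


class TestRunProtocol:
    def test_sample_count(self):
        r = run_protocol("single", None, StimulusProtocol(duration=2000.0))
        assert len(r.time) == 20001
        assert len(r.v_soma) == 20001

    def test_determinism(self):
        proto = constant_current_protocol(2.0, stim_duration=300.0)
        a = run_protocol("single", None, proto)
        b = run_protocol("single", None, proto)
        assert np.array_equal(a.v_soma, b.v_soma)
        assert np.array_equal(a.soma_spikes, b.soma_spikes)

    def test_unknown_model_rejected(self):
        with pytest.raises(ConfigurationError):
            run_protocol("three", None, StimulusProtocol(duration=10.0))

    def test_bad_protocol_rejected(self):
        with pytest.raises(ConfigurationError):
            StimulusProtocol(duration=10.05, dt=0.1)
        with pytest.raises(ConfigurationError):
            StimulusProtocol(duration=0.0)


class TestDetectSpikes:
    def test_flat_trace_empty(self):
        assert len(detect_spikes(np.full(100, -65.0), 0.1)) == 0

    def test_single_crossing_at_known_sample(self):
        tr = np.full(50, -65.0)
        tr[30:] = 0.0
        sp = detect_spikes(tr, 0.1)
        assert list(sp) == [pytest.approx(3.0)]

    def test_plateau_counts_once(self):
        tr = np.full(100, -65.0)
        tr[20:70] = -10.0
        assert len(detect_spikes(tr, 0.1)) == 1

    def test_rearms_after_falling_below(self):
        tr = np.full(100, -65.0)
        tr[20:30] = 0.0
        tr[50:60] = 0.0
        assert len(detect_spikes(tr, 0.1)) == 2


class TestInitialState:
    def test_soma_starts_at_gate_equilibrium(self):
        s = initial_state("soma")
        eq = gating_equilibrium(s.v)
        assert s.gates.m == eq.m_inf and s.gates.n == eq.n_inf

    def test_dendrite_starts_eligible(self):
        s = initial_state("dend")
        assert not s.dcaap.active and s.dcaap.t_prime is None
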