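"""Trace comparison, mode sweeps and the LUT resolution study."""

import copy

import numpy as np
import pytest

from pyramidal.errors import ComparisonError
from pyramidal.solver import run_protocol
from pyramidal.validation import (
    compare_traces,
    constant_current_protocol,
    current_sweep,
    lut_resolution_study,
    serialize_reports,
)


@pytest.fixture(scope="module")
def short_run():
    return run_protocol("single", None, constant_current_protocol(3.0, stim_duration=400.0))


class TestCompareTraces:
    def test_self_comparison_is_zero(self, short_run):
        rep = compare_traces(short_run, short_run)
        assert rep.max_abs_voltage_error["soma"] == 0.0
        assert rep.max_spike_delta == 0.0
        assert not rep.spike_count_mismatch

    def test_one_sample_shift_gives_one_step_deltas(self, short_run):
        shifted = copy.copy(short_run)
        shifted.v_soma = np.roll(short_run.v_soma, 1)
        shifted.v_soma[0] = short_run.v_soma[0]
        from pyramidal.solver import detect_spikes

        shifted.soma_spikes = detect_spikes(shifted.v_soma, short_run.dt)
        rep = compare_traces(short_run, shifted)
        deltas = rep.spike_deltas["soma"]
        assert len(deltas) >= 2
        assert np.allclose(deltas, 0.1)

    def test_grid_mismatch_rejected(self, short_run):
        other = run_protocol(
            "single", None, constant_current_protocol(3.0, stim_duration=500.0)
        )
        with pytest.raises(ComparisonError):
            compare_traces(short_run, other)

    def test_count_mismatch_flagged(self, short_run):
        other = run_protocol(
            "single", None, constant_current_protocol(0.0, stim_duration=400.0)
        )
        rep = compare_traces(short_run, other)
        assert rep.spike_count_mismatch


class TestCurrentSweep:
    def test_zero_current_rest_state_error_bounded_by_quantization(self):
        reports = current_sweep(currents=[0.0], stim_duration=300.0)
        rep = reports[0]
        assert len(rep.spike_deltas["soma"]) == 0
        # at rest the fixed trajectory differs only through quantization of
        # the near-constant state; a generous multiple of the s16.15 step
        assert rep.max_abs_voltage_error["soma"] < 100 * 2.0**-15

    def test_fixed_vs_double_spike_deltas_single_step(self):
        reports = current_sweep(currents=[1.0, 3.0], stim_duration=1000.0)
        for rep in reports:
            assert not rep.spike_count_mismatch
            assert rep.max_spike_delta <= 0.1 + 1e-9

    def test_dendritic_sweep_counts_consistent_across_modes(self):
        reports = current_sweep(
            model="two",
            compartment="dend",
            currents=[0.0, 2.0, 3.0],
            stim_duration=1000.0,
        )
        for rep in reports:
            assert not rep.spike_count_mismatch

    def test_determinism(self):
        a = current_sweep(currents=[2.0], stim_duration=300.0)
        b = current_sweep(currents=[2.0], stim_duration=300.0)
        assert a[0].max_abs_voltage_error == b[0].max_abs_voltage_error
        assert np.array_equal(a[0].spike_deltas["soma"], b[0].spike_deltas["soma"])


@pytest.fixture(scope="module")
def study():
    return lut_resolution_study()


class TestLutResolutionStudy:

    def test_finer_table_more_accurate(self, study):
        assert study["1mV"] < study["2mV"]

    def test_reports_all_variants(self, study):
        assert set(study) == {"no-lut", "1mV", "2mV"}
        assert all(v >= 0 for v in study.values())

    def test_double_direct_self_error_zero(self):
        proto = constant_current_protocol(3.0, stim_duration=300.0)
        a = run_protocol("single", None, proto, arithmetic="double", gating="direct")
        b = run_protocol("single", None, proto, arithmetic="double", gating="direct")
        assert compare_traces(a, b).max_abs_voltage_error["soma"] == 0.0


class TestErrorLocalization:
    def test_dendritic_error_resets_between_dcaaps(self):
        """Between dCaAP waveforms the dendrite is passive, so the
        fixed-vs-double voltage error collapses to the quantization scale
        and does not accumulate across successive events."""
        proto = constant_current_protocol(3.0, compartment="dend")
        rd = run_protocol("two", None, proto, arithmetic="double", gating="lut")
        rf = run_protocol("two", None, proto, arithmetic="fixed", gating="lut")
        err = np.abs(rd.v_dend - rf.v_dend)
        onsets = rd.dcaap_onsets
        assert len(onsets) >= 5
        window_max = []
        quiet_max = []
        for t_on in onsets:
            k = int(round(t_on / proto.dt))
            window_max.append(err[k : k + 500].max())       # 50 ms around the event
            quiet_max.append(err[k + 800 : k + 1900].max())  # refractory stretch
        # per-event error does not grow with event index
        assert window_max[-1] <= window_max[1] * 1.5 + 1e-6
        # quiet-period error stays small (residual coupling to the soma's
        # quantized trajectory keeps it above the bare s16.15 step, but it is
        # bounded and does not grow across events)
        assert max(quiet_max) < 0.05
        assert quiet_max[-1] <= quiet_max[1] * 1.5 + 1e-9


class TestSerialization:
    def test_report_text_contains_records(self, short_run):
        rep = compare_traces(short_run, short_run)
        rep.meta["current_nA"] = 3.0
        text = serialize_reports([rep])
        assert "max_abs_voltage_error_mV" in text
        assert "current_nA\t3.0" in text
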