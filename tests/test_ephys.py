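"""Electrophysiology estimators: transient/plateau/ramp passive properties,
consolidation and QC rules, AP counting, and triangular-template EPSC
detection."""
import logging
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ineuron import synthetic as S
from ineuron.ephys import (FitFailureError, PassiveProperties, QCFlags,
                           RampProtocol, StepProtocol, Trace,
                           TriangularTemplateParams, analyze_ramp,
                           consolidate_passive, count_aps, detect_epscs,
                           epsc_frequency_transform, extract_passive,
                           fit_capacitive_transient, qc_recording,
                           rcell_from_plateau, read_trace, write_trace)

logging.getLogger("ineuron").setLevel(logging.ERROR)

STEP = StepProtocol()
RAMP = RampProtocol()


def resistor_step_traces(r_mohm=500.0, e_mv=-80.0, fs=20000.0,
                         protocol=STEP):
    """Ideal ohmic element: I = (V - E)/R, no capacitance."""
    n = int(round((protocol.step_onset + protocol.step_duration) / 1000 * fs))
    onset = int(round(protocol.step_onset / 1000 * fs))
    traces = []
    for target in protocol.step_targets:
        i = np.full(n, 1000.0 * (protocol.holding - e_mv) / r_mohm)
        i[onset:] = 1000.0 * (target - e_mv) / r_mohm
        traces.append(Trace(fs, i))
    return traces


class TestCapacitiveTransient:
    def test_noiseless_recovery_within_2pct(self):
        p = S.MembraneSimParams(rcell_mohm=500, ccell_pf=30, rs_mohm=15,
                                noise_sd_pa=0)
        traces, _ = S.simulate_voltage_clamp(p, STEP, 0)
        r = rcell_from_plateau(traces, STEP, rs_mohm=15)
        tau, c = fit_capacitive_transient(traces[0], STEP, 15,
                                          STEP.step_targets[0],
                                          rcell_mohm=r)
        assert c == pytest.approx(30.0, rel=0.02)
        assert tau == pytest.approx(p.tau_clamp_ms, rel=0.01)

    def test_uncorrected_estimate_is_tau_over_rs(self):
        p = S.MembraneSimParams(rcell_mohm=500, ccell_pf=30, rs_mohm=15,
                                noise_sd_pa=0)
        traces, _ = S.simulate_voltage_clamp(p, STEP, 0)
        tau, c = fit_capacitive_transient(traces[0], STEP, 15,
                                          STEP.step_targets[0])
        assert c == pytest.approx(tau * 1000.0 / 15.0)

    def test_zero_amplitude_step_rejected(self):
        p = S.MembraneSimParams(noise_sd_pa=0)
        traces, _ = S.simulate_voltage_clamp(p, STEP, 0)
        with pytest.raises(ValueError, match="zero-amplitude"):
            fit_capacitive_transient(traces[0], STEP, 15, STEP.holding)

    def test_monte_carlo_median_error_under_5pct(self):
        errs = []
        for seed in range(30):
            p = S.MembraneSimParams(noise_sd_pa=5.0)
            traces, _ = S.simulate_voltage_clamp(p, STEP, seed)
            r = rcell_from_plateau(traces, STEP, rs_mohm=15)
            cs = []
            for tr, tgt in zip(traces, STEP.step_targets):
                try:
                    cs.append(fit_capacitive_transient(
                        tr, STEP, 15, tgt, rcell_mohm=r)[1])
                except FitFailureError:
                    pass
            errs.append(abs(np.mean(cs) - 30.0) / 30.0)
        assert np.median(errs) < 0.05


class TestPlateauResistance:
    def test_ideal_resistor_exact(self):
        r = rcell_from_plateau(resistor_step_traces(500.0), STEP)
        assert r == pytest.approx(500.0, rel=1e-6)

    def test_two_step_equals_four_step_on_resistor(self):
        proto2 = StepProtocol(step_targets=(-95.0, -65.0))
        r2 = rcell_from_plateau(resistor_step_traces(500.0, protocol=proto2),
                                proto2)
        assert r2 == pytest.approx(500.0, rel=1e-6)

    def test_identical_targets_degenerate(self):
        proto = StepProtocol(step_targets=(-90.0, -90.0))
        with pytest.raises(ValueError, match="distinct"):
            rcell_from_plateau(resistor_step_traces(protocol=proto), proto)

    def test_simulated_cell_within_3pct(self):
        p = S.MembraneSimParams(rcell_mohm=800, ccell_pf=30, rs_mohm=15,
                                noise_sd_pa=0)
        traces, _ = S.simulate_voltage_clamp(p, STEP, 0)
        r = rcell_from_plateau(traces, STEP, rs_mohm=15)
        assert r == pytest.approx(800.0, rel=0.03)


class TestRamp:
    def ramp_resistor_trace(self, r_mohm=500.0, e_mv=-80.0, fs=20000.0):
        n = int(round((RAMP.pre_duration + RAMP.ramp_duration) / 1000 * fs)) + 1
        from ineuron.ephys import _command_voltage
        v = _command_voltage(RAMP, n, fs)
        return Trace(fs, 1000.0 * (v - e_mv) / r_mohm)

    def test_pure_resistor_exact(self):
        res = analyze_ramp(self.ramp_resistor_trace(), RAMP)
        assert res.rcell_mohm == pytest.approx(500.0, rel=1e-9)
        assert res.vrmp_mv == pytest.approx(-80.0, abs=1e-6)

    def test_passive_cell_vrmp_within_1mv(self):
        p = S.MembraneSimParams(rcell_mohm=800, ccell_pf=40, rs_mohm=15,
                                vrmp_mv=-75.0, noise_sd_pa=5.0)
        trace, _ = S.simulate_ramp(p, RAMP, 0)
        res = analyze_ramp(trace, RAMP, ccell_pf=40.0, rs_mohm=15)
        assert res.vrmp_mv == pytest.approx(-75.0, abs=1.0)
        assert res.rcell_mohm == pytest.approx(800.0, rel=0.05)

    def test_subthreshold_sodium_triggers_linear_fallback(self):
        # a sharp subthreshold sodium conductance near -55 mV distorts the
        # current before the zero crossing; the window's linear fit must be
        # used instead and still recover the true rest
        p = S.MembraneSimParams(rcell_mohm=800, ccell_pf=30, rs_mohm=15,
                                vrmp_mv=-50.0, noise_sd_pa=2.0,
                                na_gmax_ns=1.0, na_midpoint_mv=-55.0,
                                na_slope_mv=2.0)
        trace, _ = S.simulate_ramp(p, RAMP, 1)
        res = analyze_ramp(trace, RAMP, ccell_pf=30.0, rs_mohm=15)
        assert res.used_linear_fallback
        assert res.vrmp_mv == pytest.approx(-50.0, abs=2.0)

    def test_window_not_spanned_is_error(self):
        short = RampProtocol(start=-60.0, end=60.0)
        trace, _ = S.simulate_ramp(S.MembraneSimParams(noise_sd_pa=0),
                                   short, 0)
        with pytest.raises(ValueError, match="slope window"):
            analyze_ramp(trace, short)


class TestConsolidation:
    def test_agreeing_estimates_averaged(self):
        props = consolidate_passive({"a": 100.0, "b": 105.0, "c": 95.0},
                                    {"a": 30.0, "b": 31.0}, -75.0, 15.0)
        assert props.rcell_mohm == pytest.approx(100.0)
        assert not props.qc.estimator_disagreement

    def test_outlier_falls_back_to_median(self):
        props = consolidate_passive({"a": 100.0, "b": 150.0, "c": 100.0},
                                    {"a": 30.0, "b": 30.0}, -75.0, 15.0)
        assert props.rcell_mohm == pytest.approx(100.0)
        assert props.qc.estimator_disagreement

    def test_tau_is_r_times_c(self):
        props = consolidate_passive({"a": 500.0, "b": 500.0},
                                    {"a": 30.0, "b": 30.0}, -75.0, 15.0)
        assert props.tau_ms == pytest.approx(15.0)

    def test_single_estimate_is_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            consolidate_passive({"a": 100.0}, {"a": 30.0, "b": 30.0},
                                -75.0, 15.0)


def props(rs=15.0, rcell=500.0, ccell=30.0, vrmp=-75.0):
    return PassiveProperties(vrmp_mv=vrmp, rcell_mohm=rcell, ccell_pf=ccell,
                             tau_ms=rcell * ccell / 1000, rs_mohm=rs)


class TestQCFlags:
    @pytest.mark.parametrize("rs, exceeded", [(24.9, False), (25.0, False),
                                              (25.1, True), (26.0, True)])
    def test_rs_ceiling(self, rs, exceeded):
        flags = qc_recording(props(rs=15.0), props(rs=rs))
        assert flags.rs_exceeded is exceeded

    @pytest.mark.parametrize("rs0, rs1, drifted", [
        (18.0, 22.0, False), (18.0, 23.0, False), (18.0, 23.1, True)])
    def test_rs_drift(self, rs0, rs1, drifted):
        flags = qc_recording(props(rs=rs0), props(rs=rs1))
        assert flags.rs_drift_exceeded is drifted

    @pytest.mark.parametrize("r1, drifted", [
        (599.0, False), (600.0, False), (650.0, True), (390.0, True)])
    def test_initial_value_drift(self, r1, drifted):
        flags = qc_recording(props(rcell=500.0), props(rcell=r1))
        assert flags.initial_values_drifted is drifted

    @given(rs=st.floats(5.0, 40.0))
    @settings(derandomize=True, max_examples=50)
    def test_rs_flag_is_pure_threshold(self, rs):
        flags = qc_recording(props(), props(rs=rs))
        assert flags.rs_exceeded == (rs > 25.0)
        assert flags.rs_drift_exceeded == (rs - 15.0 > 5.0)


class TestAPCounting:
    def spike_trace(self, times_ms, fs=10000.0, dur_ms=500.0, base=-80.0):
        v = np.full(int(dur_ms / 1000 * fs), base)
        for t in times_ms:
            i = int(t / 1000 * fs)
            v[i:i + 10] = 10.0
        return Trace(fs, v)

    def test_stylized_three_spikes(self):
        res = count_aps([self.spike_trace([100, 200, 300])])
        assert res.per_step_counts == [3]
        assert res.max_count == 3

    def test_flat_trace_zero(self):
        assert count_aps([self.spike_trace([])]).max_count == 0

    def test_refractory_merges_fast_double_crossings(self):
        # two crossings 0.5 ms apart count once at the default 1 ms refractory
        fs = 10000.0
        v = np.full(1000, -80.0)
        v[100:103] = 0.0
        v[105:108] = 0.0
        assert count_aps([Trace(fs, v)]).max_count == 1
        assert count_aps([Trace(fs, v)], refractory_ms=0.1).max_count == 2

    def test_simulated_families_exact(self, rng):
        for _ in range(30):
            p = S.MembraneSimParams()
            counts = rng.integers(0, 31, size=20).tolist()
            currents = list(np.linspace(-20, 170, 20))
            traces, truth = S.simulate_current_clamp(p, currents, counts, rng)
            res = count_aps(traces)
            assert res.per_step_counts == truth["n_spikes"]
            assert res.max_count == truth["max_count"]

    def test_adding_a_spike_never_decreases_count(self):
        base = self.spike_trace([100, 200])
        more = self.spike_trace([100, 200, 400])
        assert (count_aps([more]).max_count
                >= count_aps([base]).max_count)


class TestEpscDetection:
    def test_planted_events_recovered(self):
        p = S.EpscTrainParams(rate_hz=10 / 60.0, amp_median_pa=60.0,
                              amp_sigma_ln=1e-9, noise_sd_pa=2.0)
        tr, truth = S.simulate_epsc_trace(p, 5)
        det = detect_epscs(tr)
        assert len(det.events) == truth["n_events"]
        assert det.frequency == pytest.approx(truth["n_events"] / 60.0)
        for ev, t in zip(det.events, truth["event_times_s"]):
            assert ev.time_s == pytest.approx(t, abs=0.002)
            assert ev.amplitude_pa == pytest.approx(60.0, rel=0.2)

    def test_oversized_event_rejected(self):
        tr, _ = S.simulate_epsc_trace(S.EpscTrainParams(rate_hz=0.0), 7)
        x = tr.samples.copy()
        kernel = S._biexp_kernel(0.5, 4.0, tr.sampling_rate)
        i0 = 30000
        x[i0:i0 + kernel.size] -= 600.0 * kernel
        det = detect_epscs(Trace(tr.sampling_rate, x))
        assert not any(abs(ev.time_s - 3.0) < 0.05 for ev in det.events)

    def test_false_positive_rate_on_pure_noise(self):
        rates = []
        for seed in range(5):
            tr, _ = S.simulate_epsc_trace(S.EpscTrainParams(rate_hz=0.0),
                                          100 + seed)
            rates.append(detect_epscs(tr).frequency)
        assert np.mean(rates) < 0.1

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="1 kHz"):
            detect_epscs(Trace(500.0, np.zeros(1000)))

    def test_event_kinetics_within_template_bounds(self):
        p = S.EpscTrainParams(rate_hz=10 / 60.0, noise_sd_pa=2.0)
        tr, _ = S.simulate_epsc_trace(p, 3)
        det = detect_epscs(tr)
        for ev in det.events:
            assert not math.isnan(ev.rise_ms) and ev.rise_ms <= 1.5 + 0.3
            assert not math.isnan(ev.fall_ms) and ev.fall_ms <= 6.0 + 0.5


class TestFrequencyTransform:
    def test_one_hertz_maps_to_zero(self):
        from ineuron.ephys import EpscDetectionResult, EpscEvent
        events = [EpscEvent(i, 50.0, 1.0, 4.0) for i in range(60)]
        res = EpscDetectionResult(events=events, duration=60.0)
        assert epsc_frequency_transform(res) == (pytest.approx(0.0), False)

    def test_six_per_minute_is_minus_one(self):
        from ineuron.ephys import EpscDetectionResult, EpscEvent
        events = [EpscEvent(i * 10.0, 50.0, 1.0, 4.0) for i in range(6)]
        res = EpscDetectionResult(events=events, duration=60.0)
        logf, zero = epsc_frequency_transform(res)
        assert logf == pytest.approx(-1.0)
        assert not zero

    def test_zero_events_flagged(self):
        from ineuron.ephys import EpscDetectionResult
        logf, zero = epsc_frequency_transform(
            EpscDetectionResult(events=[], duration=60.0))
        assert math.isnan(logf) and zero


class TestTraceIO:
    def test_round_trip(self, tmp_path):
        tr = Trace(10000.0, np.sin(np.linspace(0, 10, 5000)))
        write_trace(tr, tmp_path / "t.csv",
                    {"cell_id": "c1", "mode": "vc", "Rs_mohm": 15.0})
        tr2, meta = read_trace(tmp_path / "t.csv")
        assert meta["cell_id"] == "c1"
        assert tr2.sampling_rate == tr.sampling_rate
        assert np.allclose(tr2.samples, tr.samples, atol=1e-6)


class TestEndToEndPassive:
    def test_extract_passive_consolidates_all_methods(self):
        p = S.MembraneSimParams(rcell_mohm=600, ccell_pf=25, rs_mohm=18,
                                vrmp_mv=-72.0, noise_sd_pa=5.0)
        steps, _ = S.simulate_voltage_clamp(p, STEP, 2)
        ramp, _ = S.simulate_ramp(p, RAMP, 2)
        props = extract_passive(steps, STEP, ramp, RAMP, 18.0)
        assert props.rcell_mohm == pytest.approx(600.0, rel=0.1)
        assert props.ccell_pf == pytest.approx(25.0, rel=0.1)
        assert props.vrmp_mv == pytest.approx(-72.0, abs=1.5)
        assert props.tau_ms == pytest.approx(
            props.rcell_mohm * props.ccell_pf / 1000.0)
        assert len([k for k in props.estimates_per_method
                    if k.startswith("rcell")]) >= 2
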