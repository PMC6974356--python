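"""IPSC detection, fitting, charge and distribution comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fetalmn as f
from fetalmn.events import (CHARGE_R_GATE, EventFit, analyze_trace,
                            compare_distributions, detect_events,
                            event_charge, fit_event, mann_whitney,
                            tonic_shift)
from fetalmn.synth import IPSCGenSpec, dual_exp_template, gen_ipsc_trace
from fetalmn.traces import Trace


def make_trace(samples, fs=20000.0, units="pA"):
    return Trace(1.0 / fs, np.asarray(samples, float), units=units)


def clean_event_trace(onsets_s, amp=50.0, tau_r=1.1, tau_d=20.0,
                      duration=1.0, noise=0.0, seed=0, fs=20000.0):
    spec = IPSCGenSpec(duration=duration, mean_iei_ms=1e12, amp_mean_pa=amp,
                       amp_cv=0.0, tau_rise_ms=tau_r, tau_decay_ms=tau_d,
                       noise_sd_pa=noise, lowpass_hz=0.0, seed=seed, fs_hz=fs)
    rng = np.random.default_rng(seed)
    n = int(duration * fs)
    sig = rng.normal(0.0, noise, n) if noise > 0 else np.zeros(n)
    t = np.arange(n) / fs
    for on in onsets_s:
        sig -= amp * dual_exp_template(t - on, tau_r * 1e-3, tau_d * 1e-3)
    if noise > 0:
        # Same 2 kHz anti-alias chain the recordings use.
        from scipy import signal as sps
        sos = sps.butter(4, 2000.0, fs=fs, output="sos")
        sig = sps.sosfiltfilt(sos, sig)
    return make_trace(sig, fs)


class TestDetect:
    def test_flat_noise_has_no_events(self):
        rng = np.random.default_rng(3)
        tr = make_trace(rng.normal(0, 2.0, 40000))
        assert detect_events(tr, threshold=15.0).size == 0

    def test_three_events_within_1ms(self):
        onsets = [0.2, 0.5, 0.8]
        tr = clean_event_trace(onsets, amp=50.0)
        det = detect_events(tr, threshold=15.0, refractory=5.0)
        assert det.size == 3
        assert np.all(np.abs(det - np.array(onsets)) < 1e-3)

    def test_threshold_above_peaks_finds_nothing(self):
        tr = clean_event_trace([0.2, 0.5, 0.8], amp=50.0)
        assert detect_events(tr, threshold=60.0).size == 0

    def test_count_monotone_in_threshold(self):
        tr, _ = gen_ipsc_trace(f.synth.preset("WT-mIPSC", seed=5,
                                              duration=20.0))
        counts = [detect_events(tr, threshold=th).size
                  for th in (10.0, 15.0, 25.0, 40.0, 60.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_voltage_trace_rejected(self):
        tr = make_trace(np.zeros(100), units="mV")
        with pytest.raises(ValueError):
            detect_events(tr)


class TestFit:
    def test_noise_free_tau_decay_recovered(self):
        tr = clean_event_trace([0.3], amp=50.0, tau_d=20.0)
        fit = fit_event(tr, 0.3)
        assert fit.tau_decay == pytest.approx(20.0, abs=0.1)
        assert fit.peak_amplitude == pytest.approx(50.0, rel=0.02)

    def test_pure_exponential_exact(self):
        # A decay with no rising phase matches the fit family exactly.
        fs = 20000.0
        t = np.arange(int(0.3 * fs)) / fs
        sig = -60.0 * np.exp(-np.maximum(t - 0.05, 0) / 16.11e-3)
        sig[t < 0.05] = 0.0
        fit = fit_event(make_trace(sig, fs), 0.05)
        assert fit.tau_decay == pytest.approx(16.11, abs=0.05)
        assert fit.r_fit == pytest.approx(1.0, abs=1e-6)

    def test_monte_carlo_tau_recovery_within_5pct(self):
        taus = []
        for s in range(60):
            tr = clean_event_trace([0.3], amp=52.8, tau_r=1.25, tau_d=20.5,
                                   duration=1.0, noise=5.0, seed=s)
            det = detect_events(tr, threshold=15.0)
            near = det[np.abs(det - 0.3) < 2e-3]
            if near.size == 0:
                continue
            fit = fit_event(tr, near[0])
            if fit.ok:
                taus.append(fit.tau_decay)
        assert len(taus) > 50
        assert np.mean(taus) == pytest.approx(20.5, rel=0.05)


class TestCharge:
    def test_reference_value(self):
        fit = EventFit(onset=0.0, peak_amplitude=52.8, tau_rise=1.25,
                       tau_decay=20.53, r_fit=0.999)
        assert event_charge(fit) == pytest.approx(1.30, abs=0.01)

    def test_pure_exponential_limit(self):
        fit = EventFit(onset=0.0, peak_amplitude=100.0, tau_rise=1e-9,
                       tau_decay=10.0, r_fit=0.999)
        assert event_charge(fit) == pytest.approx(1.0, rel=1e-6)

    def test_gate_below_threshold_gives_none(self):
        fit = EventFit(onset=0.0, peak_amplitude=50.0, tau_rise=1.0,
                       tau_decay=20.0, r_fit=0.9)
        assert event_charge(fit) is None

    def test_shape_error_when_decay_not_slower(self):
        fit = EventFit(onset=0.0, peak_amplitude=50.0, tau_rise=20.0,
                       tau_decay=5.0, r_fit=0.999)
        with pytest.raises(ValueError):
            event_charge(fit)

    @settings(deadline=None, max_examples=30)
    @given(st.floats(10, 100), st.floats(0.3, 3.0), st.floats(5.0, 40.0))
    def test_matches_numerical_integration(self, amp, tau_r, tau_d):
        # The closed form must agree with quadrature of the fitted template.
        if tau_d <= tau_r * 1.5:
            return
        fit = EventFit(onset=0.0, peak_amplitude=amp, tau_rise=tau_r,
                       tau_decay=tau_d, r_fit=0.999)
        t = np.linspace(0, 30 * tau_d, 400000) * 1e-3
        y = amp * dual_exp_template(t, tau_r * 1e-3, tau_d * 1e-3)
        numeric = np.trapezoid(y, t)
        assert event_charge(fit) == pytest.approx(numeric, rel=5e-3)


class TestTonic:
    def test_pure_step(self):
        n = 200000     # 10 s at 20 kHz
        sig = np.zeros(n)
        sig[n // 2:] += 12.0
        shift = tonic_shift(make_trace(sig), t_switch=5.0, settle=4.0)
        assert shift == pytest.approx(12.0, abs=0.01)

    def test_step_with_superimposed_events(self):
        spec = IPSCGenSpec(duration=20.0, mean_iei_ms=1000.0,
                           amp_mean_pa=50.0, noise_sd_pa=2.0,
                           tonic_steps=((10.0, 12.0),), seed=4)
        tr, _ = gen_ipsc_trace(spec)
        shift = tonic_shift(tr, t_switch=10.0, settle=5.0)
        assert shift == pytest.approx(12.0, abs=1.0)

    def test_null_case(self):
        spec = IPSCGenSpec(duration=20.0, mean_iei_ms=1000.0,
                           amp_mean_pa=50.0, noise_sd_pa=2.0, seed=9)
        tr, _ = gen_ipsc_trace(spec)
        assert tonic_shift(tr, t_switch=10.0, settle=5.0) == pytest.approx(
            0.0, abs=1.0)

    def test_insufficient_baseline_rejected(self):
        tr = make_trace(np.zeros(20000))
        with pytest.raises(ValueError):
            tonic_shift(tr, t_switch=0.1, settle=5.0)


class TestDistributions:
    def test_identical_samples_d_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        d, _ = compare_distributions(x, x)
        assert d == 0.0

    def test_disjoint_supports_d_one(self):
        d, p = compare_distributions([1, 2, 3], [4, 5, 6])
        assert d == 1.0

    def test_shifted_uniform_d_half(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, 1000)
        y = rng.uniform(0.5, 1.5, 1000)
        d, p = compare_distributions(x, y)
        assert d == pytest.approx(0.5, abs=0.05)
        assert p < 1e-10

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compare_distributions([], [1.0])
        with pytest.raises(ValueError):
            mann_whitney([1.0], [])


class TestPipeline:
    def test_truncated_overlapping_events_flagged(self):
        tr = clean_event_trace([0.2, 0.25], amp=60.0, tau_d=30.0)
        es = analyze_trace(tr, threshold=15.0)
        assert len(es.events) == 2
        assert es.events[0].truncated

    def test_iei_matches_onset_differences(self):
        tr, truth = gen_ipsc_trace(f.synth.preset("SOD-mIPSC", seed=2,
                                                  duration=30.0))
        es = analyze_trace(tr)
        assert es.iei.size == len(es.events) - 1
        onsets = np.array([e.onset for e in es.events])
        assert np.allclose(np.diff(onsets) * 1e3, es.iei)
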