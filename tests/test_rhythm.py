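"""Locomotor rhythm: envelopes, burst starts, period, circular phase."""

import numpy as np
import pytest

from fetalmn.rhythm import (BurstSeries, cycle_period, detect_burst_starts,
                            mean_frequency_envelope, phase_and_rayleigh,
                            rayleigh_test)
from fetalmn.synth import BurstGenSpec, gen_alternating_bursts, \
    gen_burst_spike_trains
from fetalmn.traces import Trace


class TestEnvelope:
    def test_regular_train_flat_at_rate(self):
        spikes = np.arange(0.05, 20.0, 0.1)     # 10 Hz
        env = mean_frequency_envelope(spikes, window=1.0)
        interior = env.samples[env.index_at(2.0):env.index_at(18.0)]
        assert np.allclose(interior, 10.0, atol=1.0)

    def test_empty_spikes_zero_envelope(self):
        env = mean_frequency_envelope([], window=0.5, duration=10.0)
        assert np.all(env.samples == 0.0)

    def test_spike_count_conserved(self):
        rng = np.random.default_rng(7)
        spikes = np.sort(rng.uniform(0, 50, 300))
        env = mean_frequency_envelope(spikes, window=0.5, duration=51.0)
        integral = np.sum(env.samples) * env.dt
        assert integral == pytest.approx(300, abs=1)

    def test_alternating_bursts_peak_and_trough(self):
        left, _, truth = gen_burst_spike_trains(
            BurstGenSpec(period=2.0, intra_rate_hz=40.0, jitter=0.0,
                         duration=60.0, seed=1))
        env = mean_frequency_envelope(left, window=0.5)
        assert env.samples.max() == pytest.approx(40.0, rel=0.15)
        assert env.samples.min() == pytest.approx(0.0, abs=1.0)


class TestBurstStarts:
    def test_square_wave_period_exact(self):
        t = np.arange(0, 40, 0.01)
        env = Trace(0.01, ((t % 2.0) < 1.0).astype(float) * 30.0, units="Hz")
        bs = detect_burst_starts(env)
        d = np.diff(bs.starts)
        assert np.allclose(d, 2.0, atol=0.02)

    def test_sinusoid_period(self):
        t = np.arange(0, 60, 0.01)
        env = Trace(0.01, 20 + 15 * np.sin(2 * np.pi * t / 1.88), units="Hz")
        bs = detect_burst_starts(env)
        assert np.allclose(np.diff(bs.starts), 1.88, atol=0.01)

    def test_flat_envelope_empty(self):
        env = Trace(0.01, np.full(1000, 5.0), units="Hz")
        assert detect_burst_starts(env).n == 0


class TestPeriod:
    def test_exact_arithmetic(self):
        bs = BurstSeries(np.array([0.0, 2.0, 4.0, 6.0]))
        assert cycle_period(bs) == (2.0, 0.0)

    def test_preset_period_recovery(self):
        left, right, truth = gen_alternating_bursts(
            BurstGenSpec(period=2.01, phase=0.49, jitter=0.02,
                         duration=100.0, seed=3))
        mean, sd = cycle_period(left)
        assert mean == pytest.approx(2.01, abs=0.03)

    def test_two_starts_insufficient(self):
        with pytest.raises(ValueError):
            cycle_period(BurstSeries(np.array([0.0, 2.0])))


class TestPhase:
    def test_perfect_antiphase(self):
        left = BurstSeries(np.arange(0.0, 40.0, 2.0))
        right = BurstSeries(np.arange(1.0, 40.0, 2.0), side="right")
        res = phase_and_rayleigh(left, right)
        assert res.mean_phase == pytest.approx(0.5, abs=1e-9)
        assert res.r == pytest.approx(1.0, abs=1e-9)

    def test_rayleigh_closed_form_identical_phases(self):
        # n identical phases: r = 1, Z = n, p = e^-n (1 + (2n - n²)/(4n)).
        n = 20
        _, r, p = rayleigh_test(np.full(n, 0.3))
        assert r == pytest.approx(1.0)
        # At Z = n = 20 the correction series has left its validity range,
        # so the tail probability reduces to the leading term exp(-Z).
        assert p == pytest.approx(np.exp(-20), rel=1e-9)
        assert p == pytest.approx(2.1e-9, rel=0.05)

    def test_uniform_null_not_significant(self):
        rng = np.random.default_rng(1)
        left = BurstSeries(np.arange(0.0, 2002.0, 2.0))
        right = BurstSeries(np.sort(np.arange(0.0, 2000.0, 2.0)
                                    + rng.uniform(0.01, 1.99, 1000)),
                            side="right")
        res = phase_and_rayleigh(left, right)
        assert res.r < 0.06
        assert res.rayleigh_p > 0.05

    def test_time_shift_invariance(self):
        left, right, _ = gen_alternating_bursts(
            BurstGenSpec(period=2.0, phase=0.5, jitter=0.02, duration=80.0,
                         seed=5))
        res = phase_and_rayleigh(left, right)
        shifted = phase_and_rayleigh(
            BurstSeries(left.starts + 13.7),
            BurstSeries(right.starts + 13.7, side="right"))
        assert shifted.mean_phase == pytest.approx(res.mean_phase, abs=1e-9)

    def test_swap_maps_phase_to_complement(self):
        left, right, _ = gen_alternating_bursts(
            BurstGenSpec(period=2.0, phase=0.4, jitter=0.01, duration=80.0,
                         seed=6))
        fwd = phase_and_rayleigh(left, right)
        rev = phase_and_rayleigh(
            BurstSeries(right.starts), BurstSeries(left.starts, side="right"))
        miss = (fwd.mean_phase + rev.mean_phase) % 1.0
        assert min(miss, 1.0 - miss) < 0.05

    def test_in_phase_generator(self):
        left, right, _ = gen_alternating_bursts(
            BurstGenSpec(period=2.0, phase=0.0, jitter=0.01, duration=80.0,
                         seed=8))
        res = phase_and_rayleigh(left, right)
        assert min(res.mean_phase, 1 - res.mean_phase) < 0.02

    def test_recovery_on_locomotion_preset(self):
        # Alternating generator (period 2.0 s, phase 0.5, 2% jitter):
        # recovered phase within [0.47, 0.53] and Rayleigh p < 0.001.
        left, right, _ = gen_alternating_bursts(
            BurstGenSpec(period=2.0, phase=0.5, jitter=0.02, duration=100.0,
                         seed=10))
        res = phase_and_rayleigh(left, right)
        assert 0.47 <= res.mean_phase <= 0.53
        assert res.rayleigh_p < 1e-3
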