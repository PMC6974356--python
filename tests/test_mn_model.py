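"""Motoneuron model: discretization, passive limits, synapses, spikes."""

import numpy as np
import pytest

import fetalmn as f
from fetalmn.model import channels
from fetalmn.model.core import integrate
from fetalmn.model.mn import (SimProtocol, SynapticTrain, detect_spikes,
                              dual_exp_norm, firing_rate, simulate)
from fetalmn.model.morphology import Section, flatten, nseg_dlambda
from fetalmn.traces import Trace


class TestDLambda:
    def test_short_section_single_segment(self):
        assert nseg_dlambda(1e-6, 1.0) == 1

    def test_reference_formula_value(self):
        # L=200 µm, diam 1 µm, Ra 100, cm 1: lambda_100 ≈ 282.1 µm -> 7.
        assert nseg_dlambda(200.0, 1.0, 100.0, 1.0) == 7

    def test_monotone_in_length(self):
        vals = [nseg_dlambda(L, 1.0) for L in np.arange(10, 2000, 10)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert all(v % 2 == 1 for v in vals)

    def test_flatten_is_parent_ordered(self, wt_model):
        p = wt_model.comp.parent
        assert p[0] == -1
        assert np.all(p[1:] < np.arange(1, p.size))

    def test_axon_has_750_segments(self, wt_model):
        start, stop = wt_model.comp.sec_slices["axon"]
        assert stop - start == 750

    def test_all_dlambda_sections_odd(self, wt_model):
        for sec in wt_model.sections:
            if sec.nseg is None:
                assert sec.resolved_nseg() % 2 == 1


def _single_compartment_arrays(area_cm2=1e-4, rm=21200.0, el=-73.0):
    gl = area_cm2 / rm * 1e6     # µS
    z = np.zeros(1)
    return {
        "parent": np.array([-1], dtype=np.int32), "g_ax": z.copy(),
        "cm": np.array([area_cm2 * 1e3]), "gl": np.array([gl]), "el": el,
        "gna": z.copy(), "gk": z.copy(), "gia": z.copy(), "gic": z.copy(),
        "gil": z.copy(),
        "ca_gain": z.copy(), "kt": 2.5e-4, "kd": 1e-4, "ca0": 2.4e-4,
        "cainf": 2e-4, "taur": 1e10, "cao": 3.0, "kc": 1e-3, "tau_o": 60.0,
        "ena": 50.0, "ek": -77.0,
    }


def _run_single(arrays, nsteps, dt, waveform):
    tables = channels.build_gate_tables(dt)
    syn = {k: np.empty(0, dtype=np.int32) if k in ("comp", "ev_syn") else
           np.empty(0, dtype=np.int64) if k == "ev_step" else np.empty(0)
           for k in ("comp", "gw", "er", "ed", "e", "ev_step", "ev_syn",
                     "ev_w")}
    inj = {"comp": 0, "waveform": waveform}
    return integrate(nsteps, dt, arrays, tables, syn, inj, [0])


class TestPassiveLimit:
    def test_isolated_compartment_rin_closed_form(self):
        # Rm 21200 Ω·cm² over 1e-4 cm² -> 212 MΩ exactly.
        arrays = _single_compartment_arrays()
        dt = 0.025
        nsteps = int(2000 / dt)
        wave = np.zeros(nsteps)
        wave[int(1000 / dt):] = -0.01    # -10 pA
        out = _run_single(arrays, nsteps, dt, wave)
        v = out["v"][:, 0]
        dv = v[-1] - v[int(1000 / dt) - 1]
        rin = dv / (-0.01)
        assert rin == pytest.approx(212.0, rel=5e-3)

    def test_resting_potential_equals_leak_reversal(self, wt_model):
        out = simulate(wt_model, SimProtocol(tstop_ms=1000))
        assert out["soma"].samples[-1] == pytest.approx(-73.0, abs=1.0)

    def test_calcium_stays_at_rest_without_influx(self):
        arrays = _single_compartment_arrays()
        arrays["ca_gain"] = np.array([1.0])   # pool present, no I_L
        dt = 0.025
        nsteps = int(500 / dt)
        out = _run_single(arrays, nsteps, dt, np.zeros(nsteps))
        assert np.all(np.abs(out["ca"] - 2.4e-4) < 1e-9)


class TestSynapse:
    def test_conductance_peaks_at_gmax_and_peak_time(self, wt_model):
        tau_r, tau_d = 0.3, 20.0
        g_max = 0.002
        syn = SynapticTrain(event_times_ms=(50.0,), tau_rise=tau_r,
                            tau_decay=tau_d, e_rev=-50.0, g_max=g_max)
        out = simulate(wt_model, SimProtocol(tstop_ms=200, synapses=(syn,)))
        g = out["g_syn"]
        assert g.max() == pytest.approx(g_max, rel=5e-3)
        t_peak_ms = np.argmax(g) * 0.025 - 50.0
        expected = tau_r * tau_d / (tau_d - tau_r) * np.log(tau_d / tau_r)
        assert t_peak_ms == pytest.approx(expected, abs=0.1)

    def test_norm_factor_below_one(self):
        assert 0 < dual_exp_norm(0.3, 20.0) < 1


class TestSpikes:
    def test_subthreshold_trace_empty(self):
        tr = Trace(1e-4, np.full(1000, -70.0), units="mV")
        assert detect_spikes(tr).size == 0

    def test_rate_arithmetic(self):
        spikes = np.linspace(0.0, 1.96, 25)   # 25 spikes in 2 s
        assert firing_rate(spikes, (0.0, 2.0)) == pytest.approx(12.5)

    def test_sinusoid_crossings(self):
        t = np.arange(0, 2, 1e-4)
        tr = Trace(1e-4, 30 * np.sin(2 * np.pi * 10 * t) - 10, units="mV")
        spikes = detect_spikes(tr, crossing=0.0)
        assert firing_rate(spikes, (0.0, 2.0)) == pytest.approx(10.0,
                                                                abs=0.5)

    def test_refractory_merges_chatter(self):
        t = np.arange(0, 0.01, 1e-5)
        v = np.where((t * 1e3 % 0.2) < 0.1, 10.0, -10.0)   # 5 kHz chatter
        tr = Trace(1e-5, v, units="mV")
        assert detect_spikes(tr, refractory_ms=1.0).size <= 10


class TestNumerics:
    def test_spike_times_converge_under_dt_halving(self, wt_model):
        def spikes_at(dt):
            prot = SimProtocol(tstop_ms=1500, dt_ms=dt,
                               injections=((100.0, 1500.0, 250.0, 250.0),))
            return detect_spikes(simulate(wt_model, prot)["soma"])
        s1 = spikes_at(0.025)
        s2 = spikes_at(0.0125)
        # Per-spike timing over the initial discharge; over longer runs the
        # small relative period error accumulates as phase drift, as for
        # any fixed-step scheme.
        n = min(s1.size, s2.size, 3)
        assert n >= 3
        assert np.all(np.abs(s1[:n] - s2[:n]) < 1e-4)   # < 0.1 ms

    def test_determinism(self, wt_model):
        prot = SimProtocol(tstop_ms=300,
                           injections=((50.0, 300.0, 250.0, 250.0),))
        a = simulate(wt_model, prot)["soma"].samples
        b = simulate(wt_model, prot)["soma"].samples
        assert np.array_equal(a, b)


class TestCanonical:
    def test_sod_terminal_dendrites_scaled(self, wt_model, sod_model):
        for sec_w, sec_s in zip(wt_model.sections, sod_model.sections):
            if sec_w.name.endswith("_term"):
                assert sec_s.length == pytest.approx(0.6 * sec_w.length)
            else:
                assert sec_s.length == sec_w.length

    def test_soma_ic_density_reference_value(self, wt_model):
        assert wt_model.config.g_ic == pytest.approx(0.0025)

    def test_invalid_override_rejected(self):
        with pytest.raises(ValueError):
            f.build_canonical_mn("WT", rm=-5.0)
        with pytest.raises(ValueError):
            f.build_canonical_mn("XX")

    def test_threshold_monotone_in_ais_na(self):
        thrs = []
        for gna in (0.3, 0.5, 0.8):
            m = f.build_canonical_mn("WT", gna_ais=gna)
            thrs.append(f.measure_spike_threshold(m))
        assert thrs[0] > thrs[1] > thrs[2]
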