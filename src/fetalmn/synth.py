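"""Synthetic electrophysiology generators with ground truth.

Every analysis stage in this package can be exercised on data produced here:
voltage-clamp traces carrying miniature/spontaneous IPSCs, agonist I/V
series, voltage-ramp current pairs, and paired left/right locomotor burst
series.  Each generator is seed-deterministic (identical spec + seed give
bit-identical output) and returns the generating ground truth alongside the
data, so parameter-recovery tests can compare the analysis output with what
was actually put in.

The IPSC generator emulates the recording chain the analyses were designed
for: events are downward dual-exponential transients on a noisy baseline,
sampled at 20 kHz and low-pass filtered at 2 kHz.  Presets parameterize the
generators with the summary statistics measured in fetal (E17.5) wild-type
and SOD1^G93A mouse motoneurons: miniature IPSCs with mean amplitude
57.9/52.8 pA, decay time constant 16.11/20.53 ms and mean inter-event
interval 838/887 ms (WT/SOD mIPSC); spontaneous IPSCs with amplitude
61.7/68.0 pA, decay 21.89/23.58 ms, IEI 157.9/182.3 ms; locomotor-like
bursting with cycle period 1.88/2.01 s and left-right phase near 0.5.
Amplitudes are drawn lognormal (only means are constrained; CV defaults to
0.4) and inter-event intervals are exponential (Poisson events).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .chloride import IVSeries, RampPair
from .rhythm import BurstSeries
from .traces import Trace

__all__ = [
    "IPSCGenSpec", "BurstGenSpec", "PRESETS",
    "gen_ipsc_trace", "gen_iv_series", "gen_alternating_bursts",
    "gen_ramp_pair", "dual_exp_template", "dual_exp_peak_time",
]


def dual_exp_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time to peak of ``exp(-t/tau_decay) - exp(-t/tau_rise)`` (same units)."""
    if not 0 < tau_rise < tau_decay:
        raise ValueError("need 0 < tau_rise < tau_decay")
    return (tau_rise * tau_decay / (tau_decay - tau_rise)
            * np.log(tau_decay / tau_rise))


def dual_exp_template(t: np.ndarray, tau_rise: float, tau_decay: float
                      ) -> np.ndarray:
    """Peak-normalized dual-exponential waveform evaluated at times ``t``.

    Zero for t < 0, rises with ``tau_rise``, relaxes with ``tau_decay`` and
    reaches exactly 1 at the analytic peak time.
    """
    tp = dual_exp_peak_time(tau_rise, tau_decay)
    norm = np.exp(-tp / tau_decay) - np.exp(-tp / tau_rise)
    out = np.where(t >= 0,
                   (np.exp(-np.maximum(t, 0) / tau_decay)
                    - np.exp(-np.maximum(t, 0) / tau_rise)) / norm,
                   0.0)
    return out


@dataclass(frozen=True)
class IPSCGenSpec:
    """Recipe for a synthetic voltage-clamp IPSC trace.

    ``mean_iei_ms`` sets the Poisson event rate; amplitudes are lognormal
    with the given mean (pA) and coefficient of variation.  ``tonic_steps``
    are (time_s, delta_pA) holding-current offsets applied from that time
    onward (a step to more inward current is a negative delta, matching the
    downward-event convention).
    """

    duration: float = 100.0            # s
    mean_iei_ms: float = 838.0
    amp_mean_pa: float = 57.9
    amp_cv: float = 0.4
    tau_rise_ms: float = 1.11
    tau_decay_ms: float = 16.11
    noise_sd_pa: float = 3.0
    tonic_steps: tuple = ()            # ((time_s, delta_pA), ...)
    fs_hz: float = 20000.0
    lowpass_hz: float = 2000.0
    baseline_pa: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("duration", "mean_iei_ms", "amp_mean_pa", "tau_rise_ms",
                     "tau_decay_ms", "fs_hz"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd_pa < 0 or self.amp_cv < 0:
            raise ValueError("noise_sd_pa and amp_cv must be non-negative")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass(frozen=True)
class BurstGenSpec:
    """Recipe for paired alternating locomotor burst trains."""

    period: float = 1.88               # s
    phase: float = 0.5                 # right start offset, cycles
    intra_rate_hz: float = 40.0
    duty_cycle: float = 0.5
    jitter: float = 0.02               # SD of start jitter, fraction of period
    duration: float = 100.0            # s
    seed: int = 0

    def __post_init__(self):
        if not self.period > 0 or not self.duration > 0:
            raise ValueError("period and duration must be positive")
        if not 0 <= self.jitter < 0.2:
            raise ValueError("jitter must be in [0, 0.2)")
        if not 0 < self.duty_cycle < 1:
            raise ValueError("duty_cycle must be in (0, 1)")
        if self.seed is None:
            raise ValueError("seed is mandatory")


#: Generator presets parameterized from measured fetal mouse statistics.
PRESETS: dict[str, object] = {
    "WT-mIPSC": IPSCGenSpec(mean_iei_ms=838.0, amp_mean_pa=57.9,
                            tau_rise_ms=1.11, tau_decay_ms=16.11),
    "SOD-mIPSC": IPSCGenSpec(mean_iei_ms=887.0, amp_mean_pa=52.8,
                             tau_rise_ms=1.25, tau_decay_ms=20.53),
    "WT-sIPSC": IPSCGenSpec(mean_iei_ms=157.9, amp_mean_pa=61.7,
                            tau_rise_ms=1.37, tau_decay_ms=21.89),
    "SOD-sIPSC": IPSCGenSpec(mean_iei_ms=182.3, amp_mean_pa=68.0,
                             tau_rise_ms=1.38, tau_decay_ms=23.58),
    "WT-locomotion": BurstGenSpec(period=1.88, phase=0.52),
    "SOD-locomotion": BurstGenSpec(period=2.01, phase=0.49),
}


def preset(name: str, seed: int, **overrides):
    """A preset spec with the mandatory seed (and optional field overrides)."""
    return replace(PRESETS[name], seed=seed, **overrides)


def gen_ipsc_trace(spec: IPSCGenSpec) -> tuple[Trace, pd.DataFrame]:
    """Synthesize a voltage-clamp trace of downward IPSCs, with ground truth.

    Returns the trace (pA) and a DataFrame with one row per event:
    ``onset_s``, ``amp_pA`` (positive peak magnitude), ``tau_rise_ms``,
    ``tau_decay_ms``.  A boolean ``overlapping`` marker in ``Trace.meta``
    flags traces where more than half the events begin inside the previous
    event's decay window.
    """
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / spec.fs_hz
    n = int(round(spec.duration * spec.fs_hz))
    t = np.arange(n) * dt

    # Poisson event times: exponential IEIs until the trace ends.
    onsets = []
    tcur = rng.exponential(spec.mean_iei_ms * 1e-3)
    margin = 5 * spec.tau_decay_ms * 1e-3
    while tcur < spec.duration - margin:
        onsets.append(tcur)
        tcur += rng.exponential(spec.mean_iei_ms * 1e-3)
    onsets = np.asarray(onsets)

    if spec.amp_cv > 0:
        sigma = np.sqrt(np.log1p(spec.amp_cv ** 2))
        mu = np.log(spec.amp_mean_pa) - 0.5 * sigma ** 2
        amps = rng.lognormal(mu, sigma, size=onsets.size)
    else:
        amps = np.full(onsets.size, spec.amp_mean_pa)

    sig = np.full(n, spec.baseline_pa)
    # Each event: downward peak-normalized dual exponential, added over a
    # finite support window (8 decay constants).
    support = int(round(8 * spec.tau_decay_ms * 1e-3 / dt))
    tau_r = spec.tau_rise_ms * 1e-3
    tau_d = spec.tau_decay_ms * 1e-3
    tmpl = dual_exp_template(np.arange(support) * dt, tau_r, tau_d)
    for onset, amp in zip(onsets, amps):
        i0 = int(round(onset / dt))
        i1 = min(i0 + support, n)
        sig[i0:i1] -= amp * tmpl[: i1 - i0]

    for t_step, delta in spec.tonic_steps:
        sig[t >= t_step] += delta

    if spec.noise_sd_pa > 0:
        sig = sig + rng.normal(0.0, spec.noise_sd_pa, size=n)

    if spec.lowpass_hz and spec.lowpass_hz < spec.fs_hz / 2:
        sos = _signal.butter(4, spec.lowpass_hz, fs=spec.fs_hz, output="sos")
        sig = _signal.sosfiltfilt(sos, sig)

    truth = pd.DataFrame({
        "onset_s": onsets,
        "amp_pA": amps,
        "tau_rise_ms": spec.tau_rise_ms,
        "tau_decay_ms": spec.tau_decay_ms,
    })
    overlap_frac = 0.0
    if onsets.size > 1:
        overlap_frac = float(np.mean(np.diff(onsets) < support * dt))
    trace = Trace(dt, sig, units="pA",
                  meta={"overlapping": overlap_frac > 0.5,
                        "overlap_fraction": overlap_frac,
                        "spec": spec})
    return trace, truth


def gen_iv_series(e_rev: float, slope: float, holdings, noise_sd: float = 0.0,
                  seed: int = 0) -> IVSeries:
    """Linear I/V points ``I = slope·(V − e_rev) + noise`` (pA, mV)."""
    holdings = np.asarray(holdings, dtype=float)
    rng = np.random.default_rng(seed)
    currents = slope * (holdings - e_rev)
    if noise_sd > 0:
        currents = currents + rng.normal(0.0, noise_sd, size=holdings.size)
    return IVSeries(holdings, currents)


def gen_ramp_pair(e_agonist: float = -49.0, g_agonist: float = 2.0,
                  g_leak: float = 1.0, e_leak: float = -73.0,
                  grid=None, noise_sd: float = 0.0, seed: int = 0) -> RampPair:
    """Control/agonist ramp current pair with a known agonist reversal.

    Conductances in nS, potentials in mV, currents in pA.  The control ramp
    is the leak current alone; the agonist ramp adds ``g_agonist·(V −
    e_agonist)``, so the subtraction protocol should recover ``e_agonist``
    (−49 mV by default, the theoretical pipette-set E_Cl of the ramp
    protocol this emulates).
    """
    if grid is None:
        grid = np.arange(-100.0, 10.0 + 0.25, 0.5)
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    ctrl = g_leak * (grid - e_leak)
    iso = ctrl + g_agonist * (grid - e_agonist)
    if noise_sd > 0:
        ctrl = ctrl + rng.normal(0.0, noise_sd, size=grid.size)
        iso = iso + rng.normal(0.0, noise_sd, size=grid.size)
    return RampPair(grid, ctrl, iso)


def gen_alternating_bursts(spec: BurstGenSpec
                           ) -> tuple[BurstSeries, BurstSeries, dict]:
    """Paired left/right burst-start series with alternating phasing.

    Left starts recur every ``period`` seconds with Gaussian jitter
    (``jitter``·period SD); each right start sits ``phase`` cycles after the
    matching left start, with its own jitter.  Returns (left, right, truth)
    where truth records the generating period and phase.
    """
    rng = np.random.default_rng(spec.seed)
    n_cycles = int(spec.duration / spec.period)
    base = np.arange(n_cycles) * spec.period + 0.25 * spec.period
    jit = spec.jitter * spec.period
    left = base + (rng.normal(0.0, jit, n_cycles) if jit > 0 else 0.0)
    right = (base + spec.phase * spec.period
             + (rng.normal(0.0, jit, n_cycles) if jit > 0 else 0.0))
    left = np.sort(left)
    right = np.sort(right[right < spec.duration])
    truth = {"period": spec.period, "phase": spec.phase,
             "intra_rate_hz": spec.intra_rate_hz,
             "duty_cycle": spec.duty_cycle}
    return (BurstSeries(left, side="left", source_duration=spec.duration),
            BurstSeries(right, side="right", source_duration=spec.duration),
            truth)


def gen_burst_spike_trains(spec: BurstGenSpec
                           ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Left/right spike-time trains realizing the alternating burst pattern.

    Spikes occur at ``intra_rate_hz`` (regular within a burst) for
    ``duty_cycle`` of each cycle, starting at each (jittered) burst start.
    Suitable input for the spike-frequency envelope / burst-detection
    pipeline.
    """
    left_b, right_b, truth = gen_alternating_bursts(spec)
    burst_len = spec.duty_cycle * spec.period
    isi = 1.0 / spec.intra_rate_hz
    n_per = max(int(burst_len / isi), 1)

    def spikes(starts):
        out = [s + isi * np.arange(n_per) for s in starts]
        arr = np.concatenate(out) if out else np.empty(0)
        return np.sort(arr[arr < spec.duration])

    return spikes(left_b.starts), spikes(right_b.starts), truth
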