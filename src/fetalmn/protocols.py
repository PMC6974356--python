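"""Inhibitory-train protocols on the motoneuron models.

The reference experiment: depolarize the model soma with a constant current
until it fires steadily at ~12.5 Hz (the locomotor firing rate of fetal
motoneurons; 250 pA for the WT cell, 200 pA for the more excitable SOD
cell), then deliver a periodic somatic train of GABA/glycine dual-
exponential conductance events and measure how the discharge changes.
Sweeping the train frequency from 0 to 100 Hz yields an event-rate /
firing-rate curve and the *cut-off frequency* — the minimal train rate that
silences the cell completely.  Because a depolarized chloride reversal
(E_GABAAR = −50 mV) weakens and can even invert inhibition, the cut-off
frequency depends strongly on E_GABAAR and on the IPSC decay time constant:
slower decay (25 vs 20 ms) lowers the cut-off, which is the compensation
effect these protocols quantify.

Timing conventions: the tonic current runs for the whole simulation; the
train starts at t = 2 s (after the discharge has stabilized) and lasts 4 s;
rates are measured on [2.5 s, 6 s], and "silenced" means zero spikes there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .model.mn import (MNModel, SimProtocol, SynapticTrain, detect_spikes,
                       firing_rate, simulate)

__all__ = [
    "TrainProtocol", "RateCurve", "CUTOFF_NOT_REACHED",
    "calibrate_tonic", "rate_under_train", "cutoff_frequency", "rate_curve",
    "calibrate_gmax",
]

#: Sentinel returned when no frequency ≤ 100 Hz silences the cell.
CUTOFF_NOT_REACHED = float("inf")

TRAIN_ONSET_MS = 2000.0
TRAIN_DURATION_MS = 4000.0
ANALYSIS_WINDOW_S = (2.5, 6.0)
TAU_RISE_MS = 0.3


@dataclass(frozen=True)
class TrainProtocol:
    """One train condition: frequency, kinetics, reversal, drive."""

    freq: float                  # Hz
    tau_decay: float = 20.0      # ms
    e_gaba: float = -50.0        # mV
    g_max: float | None = None   # µS; None -> the model's calibrated value
    tonic_current: float = 250.0  # pA
    onset: float = TRAIN_ONSET_MS       # ms
    duration: float = TRAIN_DURATION_MS  # ms

    def __post_init__(self):
        if self.freq < 0:
            raise ValueError("freq must be non-negative")
        if not self.onset >= 2000.0:
            raise ValueError("train must start after rate stabilization "
                             "(t = 2 s)")


@dataclass
class RateCurve:
    """Firing rate vs train frequency with per-point effect classification."""

    freqs: np.ndarray
    rates: np.ndarray
    baseline: float
    effect: list = field(default_factory=list)
    tol: float = 0.5             # Hz

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.freqs.size != self.rates.size:
            raise ValueError("freqs and rates must have equal length")
        if not self.effect:
            self.effect = [self.classify(r) for r in self.rates]

    def classify(self, rate: float) -> str:
        if rate < self.baseline - self.tol:
            return "inhibitory"
        if rate > self.baseline + self.tol:
            return "excitatory"
        return "neutral"


def _run_train(model: MNModel, p: TrainProtocol) -> np.ndarray:
    """Simulate one train condition; returns somatic spike times (s)."""
    tstop = p.onset + p.duration
    g_max = p.g_max if p.g_max is not None else model.config.g_gaba_max
    synapses = ()
    if p.freq > 0:
        synapses = (SynapticTrain.periodic(
            p.freq, p.onset, p.duration, tau_rise=TAU_RISE_MS,
            tau_decay=p.tau_decay, e_rev=p.e_gaba, g_max=g_max),)
    prot = SimProtocol(
        tstop_ms=tstop,
        injections=((0.0, tstop, p.tonic_current, p.tonic_current),),
        synapses=synapses)
    v = simulate(model, prot)["soma"]
    return detect_spikes(v)


def rate_under_train(model: MNModel, p: TrainProtocol) -> float:
    """Somatic spike rate (Hz) during the train analysis window."""
    spikes = _run_train(model, p)
    t0 = max(ANALYSIS_WINDOW_S[0], (p.onset + 500.0) * 1e-3)
    t1 = (p.onset + p.duration) * 1e-3
    return firing_rate(spikes, (t0, t1))


def _steady_rate(model: MNModel, current_pa: float,
                 window_s: tuple[float, float] = (1.0, 2.0)) -> float:
    """Steady discharge rate under a constant somatic current."""
    tstop = window_s[1] * 1e3
    prot = SimProtocol(tstop_ms=tstop,
                       injections=((0.0, tstop, current_pa, current_pa),))
    v = simulate(model, prot)["soma"]
    return firing_rate(detect_spikes(v), window_s)


def calibrate_tonic(model: MNModel, target_rate: float = 12.5,
                    tol_hz: float = 0.25,
                    bracket_pa: tuple[float, float] = (0.0, 1000.0)) -> float:
    """Tonic current (pA) driving the model at ``target_rate`` Hz.

    Bisection on the steady rate measured over t ∈ [1, 2] s; converges to
    within ``tol_hz`` of the target (or to sub-pA bracket width on a rate
    plateau).  A target of 0 Hz returns the lower boundary.  Raises when the
    target exceeds the rate reachable at the upper bracket.
    """
    lo, hi = bracket_pa
    if target_rate <= 0:
        return lo
    if _steady_rate(model, hi) < target_rate:
        raise ValueError(f"target rate {target_rate} Hz unreachable "
                         f"below {hi} pA")
    r_lo = _steady_rate(model, lo)
    if r_lo >= target_rate:
        return lo
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        r = _steady_rate(model, mid)
        if abs(r - target_rate) <= tol_hz:
            return mid
        if r < target_rate:
            lo = mid
        else:
            hi = mid
        if hi - lo < 0.5:
            break
    return 0.5 * (lo + hi)


def _silenced(model: MNModel, freq: float, tau_decay: float, e_gaba: float,
              tonic_pa: float, g_max: float | None) -> bool:
    p = TrainProtocol(freq=freq, tau_decay=tau_decay, e_gaba=e_gaba,
                      g_max=g_max, tonic_current=tonic_pa)
    spikes = _run_train(model, p)
    n = np.sum((spikes >= ANALYSIS_WINDOW_S[0])
               & (spikes < ANALYSIS_WINDOW_S[1]))
    return n == 0


def cutoff_frequency(model: MNModel, tau_decay: float, e_gaba: float,
                     tonic_pa: float, g_max: float | None = None,
                     coarse_step: float = 5.0, f_max: float = 100.0,
                     refine_step: float = 1.0,
                     method: str = "bisect") -> float:
    """Minimal train frequency (Hz) that fully silences the discharge.

    The answer lives on the coarse grid 0..``f_max`` step ``coarse_step``,
    refined to ``refine_step``.  ``method="bisect"`` exploits that silencing
    is monotone in frequency (verified by construction of the grid result);
    ``method="scan"`` evaluates every grid point and warns if the silencing
    indicator is non-monotone, returning the minimal silencing frequency.
    Returns ``CUTOFF_NOT_REACHED`` (inf) if even ``f_max`` does not silence.
    """
    def silenced(f):
        return _silenced(model, f, tau_decay, e_gaba, tonic_pa, g_max)

    if not silenced(f_max):
        return CUTOFF_NOT_REACHED

    if method == "scan":
        grid = np.arange(0.0, f_max + coarse_step / 2, coarse_step)
        flags = [silenced(f) for f in grid]
        first = int(np.argmax(flags))
        if not all(flags[first:]):
            warnings.warn("silencing is non-monotone in train frequency; "
                          "returning the minimal silencing frequency")
        hi = grid[first]
        lo = hi - coarse_step
    else:
        lo, hi = 0.0, f_max
        while hi - lo > coarse_step:
            mid = lo + coarse_step * round((hi - lo) / 2 / coarse_step)
            mid = min(max(mid, lo + coarse_step), hi - coarse_step)
            if silenced(mid):
                hi = mid
            else:
                lo = mid
    if hi <= 0:
        return 0.0
    # Refine between lo and hi on the fine grid.
    while hi - lo > refine_step:
        mid = lo + refine_step * round((hi - lo) / 2 / refine_step)
        mid = min(max(mid, lo + refine_step), hi - refine_step)
        if silenced(mid):
            hi = mid
        else:
            lo = mid
    return float(hi)


def rate_curve(model: MNModel, freqs, tau_decay: float, e_gaba: float,
               tonic_pa: float, g_max: float | None = None,
               tol: float = 0.5) -> RateCurve:
    """Firing rate at each train frequency, classified vs baseline.

    The baseline is the rate with no train (freq 0); points more than
    ``tol`` Hz below it are inhibitory, above it excitatory.
    """
    freqs = np.asarray(freqs, dtype=float)
    baseline = rate_under_train(
        model, TrainProtocol(freq=0.0, tau_decay=tau_decay, e_gaba=e_gaba,
                             g_max=g_max, tonic_current=tonic_pa))
    rates = []
    for f in freqs:
        if f == 0:
            rates.append(baseline)
            continue
        rates.append(rate_under_train(
            model, TrainProtocol(freq=f, tau_decay=tau_decay, e_gaba=e_gaba,
                                 g_max=g_max, tonic_current=tonic_pa)))
    return RateCurve(freqs=freqs, rates=np.asarray(rates), baseline=baseline,
                     tol=tol)


def calibrate_gmax(model: MNModel, tonic_pa: float, freq: float = 71.0,
                   tau_decay: float = 25.0, e_gaba: float = -50.0,
                   bracket_us: tuple[float, float] = (1e-4, 0.05),
                   rel_tol: float = 0.02) -> float:
    """Smallest unitary conductance (µS) whose train silences the model.

    Used once, on the WT model, to fix the unitary GABA/glycine conductance:
    the 71 Hz, tau_decay 25 ms, E −50 mV train must just silence the WT
    discharge.  The value is then frozen in the model config and reused for
    every protocol and both genotypes.
    """
    lo, hi = bracket_us
    if not _silenced(model, freq, tau_decay, e_gaba, tonic_pa, hi):
        raise ValueError("upper conductance bracket does not silence")
    if _silenced(model, freq, tau_decay, e_gaba, tonic_pa, lo):
        raise ValueError("lower conductance bracket already silences")
    while (hi - lo) / hi > rel_tol:
        mid = np.sqrt(lo * hi)
        if _silenced(model, freq, tau_decay, e_gaba, tonic_pa, mid):
            hi = mid
        else:
            lo = mid
    return float(hi)
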