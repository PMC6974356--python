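"""Detection and characterization of inhibitory postsynaptic currents.

Voltage-clamp recordings of fetal motoneurons held at −70 mV show GABA_A/
glycine-receptor IPSCs as downward (inward-going) current deflections.  This
module finds those events, measures each one (peak amplitude, single-
exponential rise and decay time constants, fit quality, charge), quantifies
tonic-current shifts revealed by receptor blockers, and wraps the two-sample
tests used to compare event populations (Kolmogorov-Smirnov for cumulative
distributions, Mann-Whitney U for means).

Conventions
-----------
* Events are downward; amplitudes are reported as positive magnitudes.
* The baseline is a running median over 200 ms, tracking slow drifts and
  tonic steps without following individual events.
* The decay time constant comes from a least-squares single-exponential fit
  of the falling phase; the fit starts 2.5 ms after the peak so that the
  rising exponential (tau_rise ≈ 1-1.4 ms) no longer contaminates the
  fitted segment.  Fit quality ``r_fit`` is the Pearson correlation between
  the fitted and observed decay samples.
* Charge is only reported for well-fitted events (r_fit > 0.98), as
  amplitude × (tau_decay − tau_rise) × the peak-normalization factor of the
  dual-exponential template — the exact integral of that template.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .traces import Trace

__all__ = [
    "EventFit", "EventSet",
    "running_baseline", "detect_events", "fit_event", "event_charge",
    "tonic_shift", "compare_distributions", "mann_whitney", "analyze_trace",
    "CHARGE_R_GATE",
]

#: Minimum decay-fit correlation for an event's charge to be reported.
CHARGE_R_GATE = 0.98


@dataclass
class EventFit:
    """Measurements of a single IPSC."""

    onset: float            # s
    peak_amplitude: float   # pA, positive magnitude of the downward peak
    tau_rise: float         # ms
    tau_decay: float        # ms
    r_fit: float            # Pearson r of fitted vs observed decay, 0..1
    charge: float | None = None   # pA·s, present only when r_fit > gate
    rise_1090: float = np.nan     # 10-90% rise time, ms
    truncated: bool = False       # decay window cut short by the next event
    ok: bool = True               # False when the fit failed to converge

    def __post_init__(self):
        if self.ok:
            if not (self.tau_rise > 0 and self.tau_decay > 0):
                raise ValueError("time constants must be positive")
            if not 0 <= self.r_fit <= 1:
                raise ValueError("r_fit must lie in [0, 1]")
        if self.charge is not None and not self.r_fit > CHARGE_R_GATE:
            raise ValueError("charge may only be set when r_fit exceeds "
                             f"{CHARGE_R_GATE}")


@dataclass
class EventSet:
    """All fitted events of one trace, with inter-event intervals (ms)."""

    events: list
    iei: np.ndarray

    def __post_init__(self):
        onsets = np.array([e.onset for e in self.events])
        if onsets.size and np.any(np.diff(onsets) <= 0):
            raise ValueError("event onsets must be strictly increasing")
        self.iei = np.asarray(self.iei, dtype=float)
        if self.iei.size != max(len(self.events) - 1, 0):
            raise ValueError("len(iei) must equal len(events) - 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "onset_s": [e.onset for e in self.events],
            "amp_pA": [e.peak_amplitude for e in self.events],
            "tau_rise_ms": [e.tau_rise for e in self.events],
            "tau_decay_ms": [e.tau_decay for e in self.events],
            "r_fit": [e.r_fit for e in self.events],
            "charge_pAs": [e.charge if e.charge is not None else np.nan
                           for e in self.events],
            "truncated": [e.truncated for e in self.events],
        })


def running_baseline(trace: Trace, window_ms: float = 200.0) -> np.ndarray:
    """Running-median baseline of the trace (same length as the signal)."""
    w = max(int(round(window_ms * 1e-3 / trace.dt)), 3)
    ser = pd.Series(trace.samples)
    return ser.rolling(w, center=True, min_periods=1).median().to_numpy()


def detect_events(trace: Trace, threshold: float = 15.0,
                  refractory: float = 5.0,
                  baseline_window_ms: float = 200.0) -> np.ndarray:
    """Onset times (s) of downward events crossing ``threshold`` pA.

    An onset is the first sample where the baseline-subtracted signal drops
    more than ``threshold`` pA below the running-median baseline; subsequent
    crossings within ``refractory`` ms are part of the same event.  The
    result is deterministic for a fixed trace, and the number of detections
    can only decrease as the threshold is raised.
    """
    if trace.units != "pA":
        raise ValueError("event detection expects a current trace in pA")
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    if refractory < 0:
        raise ValueError("refractory must be non-negative")
    dev = trace.samples - running_baseline(trace, baseline_window_ms)
    below = dev < -threshold
    # First samples of below-threshold runs; a new event is only armed once
    # the signal has recovered above half the threshold, so noise riding on
    # a decay tail cannot re-trigger.
    starts = np.flatnonzero(below & ~np.roll(below, 1))
    if below[0]:
        starts = np.concatenate(([0], starts[starts != 0]))
    if starts.size == 0:
        return np.empty(0)
    rearm = dev > -threshold / 2
    ref_n = refractory * 1e-3 / trace.dt
    keep = [starts[0]]
    for s in starts[1:]:
        if s - keep[-1] < ref_n:
            continue
        if np.any(rearm[keep[-1]:s]):
            keep.append(s)
    return trace.t0 + np.asarray(keep) * trace.dt


def _exp_decay(t, a, tau):
    return a * np.exp(-t / tau)


def fit_event(trace: Trace, onset: float, window: float = 100.0,
              next_onset: float | None = None,
              decay_fit_delay_ms: float = 2.5,
              peak_search_ms: float = 10.0) -> EventFit:
    """Fit one downward IPSC starting near ``onset`` (s).

    ``window`` (ms) bounds the decay segment; if ``next_onset`` falls inside
    it, the segment is truncated there and the event flagged.  Returns a
    flagged :class:`EventFit` with ``ok=False`` and ``r_fit=0`` when the fit
    cannot converge, so downstream statistics can exclude it.
    """
    i_on = trace.index_at(onset)
    if not 0 <= i_on < trace.n:
        raise ValueError("onset outside trace")
    dt_ms = trace.dt * 1e3

    # Local baseline from the 5 ms preceding the detection crossing (backed
    # off 0.5 ms to avoid the event foot).
    i_b0 = max(i_on - int(round(5.0 / dt_ms)), 0)
    i_b1 = max(i_on - int(round(0.5 / dt_ms)), i_b0 + 1)
    baseline = float(np.median(trace.samples[i_b0:i_b1]))

    # Peak = minimum within the peak-search window.
    i_ps = min(i_on + int(round(peak_search_ms / dt_ms)), trace.n)
    seg = trace.samples[i_on:i_ps]
    if seg.size < 3:
        return _failed_fit(onset)
    i_pk = i_on + int(np.argmin(seg))
    amp = baseline - float(trace.samples[i_pk])
    if amp <= 0:
        return _failed_fit(onset)

    # Decay segment: from peak + delay to the window end (or next onset).
    i_end = i_on + int(round(window / dt_ms))
    truncated = False
    if next_onset is not None:
        i_next = trace.index_at(next_onset)
        if i_next < i_end:
            i_end = i_next
            truncated = True
    i_end = min(i_end, trace.n)
    i_d0 = min(i_pk + int(round(decay_fit_delay_ms / dt_ms)), i_end - 1)
    t_dec = (np.arange(i_d0, i_end) - i_d0) * dt_ms
    y_dec = baseline - trace.samples[i_d0:i_end]
    if t_dec.size < 5:
        return _failed_fit(onset)
    try:
        popt, _ = optimize.curve_fit(
            _exp_decay, t_dec, y_dec,
            p0=[max(y_dec[0], 1e-6), max(window / 5.0, 1.0)],
            bounds=([0, 1e-3], [np.inf, 10 * window]), maxfev=2000)
    except RuntimeError:
        return _failed_fit(onset)
    tau_decay = float(popt[1])
    fit_vals = _exp_decay(t_dec, *popt)
    if np.std(fit_vals) == 0 or np.std(y_dec) == 0:
        r_fit = 0.0
    else:
        r_fit = float(np.corrcoef(fit_vals, y_dec)[0, 1])
    r_fit = min(max(r_fit, 0.0), 1.0)

    # Rising phase: from the last pre-peak sample above 95% of baseline
    # (i.e. below 5% of amplitude) to the peak.
    rise_dev = baseline - trace.samples[i_on:i_pk + 1]
    above5 = np.flatnonzero(rise_dev < 0.05 * amp)
    i_r0 = i_on + (int(above5[-1]) if above5.size else 0)
    t_rise = (np.arange(i_r0, i_pk + 1) - i_r0) * dt_ms
    y_rise = baseline - trace.samples[i_r0:i_pk + 1]
    tau_rise, rise_1090 = _fit_rise(t_rise, y_rise, amp)
    if not np.isfinite(tau_rise) or tau_rise <= 0:
        # Fall back on the 10-90% rise time (2.197 tau for an exponential).
        if np.isfinite(rise_1090) and rise_1090 > 0:
            tau_rise = rise_1090 / 2.197
        else:
            tau_rise = dt_ms

    fit = EventFit(onset=onset, peak_amplitude=amp, tau_rise=tau_rise,
                   tau_decay=tau_decay, r_fit=r_fit, rise_1090=rise_1090,
                   truncated=truncated)
    if r_fit > CHARGE_R_GATE and tau_decay > tau_rise:
        fit.charge = event_charge(fit)
    return fit


def _failed_fit(onset: float) -> EventFit:
    return EventFit(onset=onset, peak_amplitude=0.0, tau_rise=np.nan,
                    tau_decay=np.nan, r_fit=0.0, ok=False)


def _fit_rise(t: np.ndarray, y: np.ndarray, amp: float
              ) -> tuple[float, float]:
    """Single-exponential approach to peak; returns (tau_rise, 10-90 time)."""
    # 10-90% rise time by linear interpolation.
    rise_1090 = np.nan
    if y.size >= 3 and amp > 0:
        frac = y / amp
        try:
            t10 = np.interp(0.1, frac, t)
            t90 = np.interp(0.9, frac, t)
            rise_1090 = max(float(t90 - t10), 0.0)
        except Exception:
            pass
    if y.size < 4:
        return np.nan, rise_1090
    p0_tau = rise_1090 / 2.197 if np.isfinite(rise_1090) and rise_1090 > 0 \
        else max(t[-1] / 3.0, 1e-3)
    try:
        popt, _ = optimize.curve_fit(
            lambda t, a, tau: a * (1 - np.exp(-t / tau)), t, y,
            p0=[amp, p0_tau], bounds=([0, 1e-4], [np.inf, 100.0]),
            maxfev=2000)
        return float(popt[1]), rise_1090
    except RuntimeError:
        return np.nan, rise_1090


def event_charge(fit: EventFit) -> float | None:
    """Charge (pA·s) of a well-fitted event, else ``None``.

    For the peak-normalized dual-exponential template the time integral is
    ``(tau_decay − tau_rise) / norm`` where ``norm`` is the template's peak
    value before normalization, so the event charge is the peak amplitude
    times that factor.  Only reported when ``r_fit`` exceeds the quality
    gate.
    """
    if not fit.r_fit > CHARGE_R_GATE:
        return None
    tau_r, tau_d = fit.tau_rise, fit.tau_decay
    if tau_d <= tau_r:
        raise ValueError("tau_decay must exceed tau_rise for a charge")
    if tau_r <= 0:
        # Pure exponential limit: charge = A * tau_d.
        return fit.peak_amplitude * tau_d * 1e-3
    tp = tau_r * tau_d / (tau_d - tau_r) * np.log(tau_d / tau_r)
    norm = np.exp(-tp / tau_d) - np.exp(-tp / tau_r)
    return float(fit.peak_amplitude * (tau_d - tau_r) / norm * 1e-3)


def tonic_shift(trace: Trace, t_switch: float, settle: float = 5.0,
                threshold: float = 15.0, refractory: float = 5.0,
                mask_after_ms: float = 100.0) -> float:
    """Tonic-current change (pA) across ``t_switch``: after − before medians.

    Event-containing stretches (from 2 ms before each detected onset to
    ``mask_after_ms`` after) are masked before taking the medians over the
    ``settle``-second windows either side of the switch, so phasic IPSCs do
    not bias the estimate of the holding-current shift.
    """
    if not (trace.t0 + settle <= t_switch <= trace.t0 + trace.duration
            - settle):
        raise ValueError("insufficient baseline on one side of t_switch")
    onsets = detect_events(trace, threshold=threshold, refractory=refractory)
    mask = np.zeros(trace.n, dtype=bool)
    for on in onsets:
        i0 = max(trace.index_at(on - 2e-3), 0)
        i1 = min(trace.index_at(on + mask_after_ms * 1e-3) + 1, trace.n)
        mask[i0:i1] = True

    def side_median(t_lo, t_hi):
        i0, i1 = trace.index_at(t_lo), trace.index_at(t_hi) + 1
        vals = trace.samples[i0:i1][~mask[i0:i1]]
        if vals.size < 10:
            raise ValueError("too few event-free samples in baseline window")
        return float(np.median(vals))

    before = side_median(t_switch - settle, t_switch - trace.dt)
    after = side_median(t_switch + trace.dt, t_switch + settle)
    return after - before


def compare_distributions(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test: (D, asymptotic p)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def mann_whitney(x, y) -> tuple[float, float]:
    """Mann-Whitney U test (two-sided): (U, p)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def analyze_trace(trace: Trace, threshold: float = 15.0,
                  refractory: float = 5.0, window: float = 100.0
                  ) -> EventSet:
    """Full pipeline: detect every event, fit it, assemble an EventSet.

    Events whose fits fail are dropped; inter-event intervals (ms) are the
    differences of the surviving onsets.
    """
    onsets = detect_events(trace, threshold=threshold, refractory=refractory)
    fits = []
    for i, on in enumerate(onsets):
        nxt = onsets[i + 1] if i + 1 < onsets.size else None
        f = fit_event(trace, on, window=window, next_onset=nxt)
        if f.ok:
            fits.append(f)
    kept = np.array([f.onset for f in fits])
    iei = np.diff(kept) * 1e3 if kept.size > 1 else np.empty(0)
    return EventSet(events=fits, iei=iei)
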