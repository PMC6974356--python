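"""Half-center central pattern generator driven by I_NaP and I_K(Ca).

The locomotor rhythm of the fetal lumbar cord is modelled as two reciprocally
inhibiting pacemaker interneurons (half-centers), each optionally driving a
follower motoneuron.  Pacemaker bursting rests on the two currents known to
underlie it in this circuit: a persistent sodium current I_NaP whose slow
inactivation paces the burst envelope, and a calcium-activated potassium
current I_K(Ca), fed by a high-threshold Ca current, that builds up during
the burst and helps terminate it.  Spiking uses the reduced
fast-Na/delayed-rectifier pair in which Na inactivation is slaved to the K
activation gate (h = 1 − n), a standard simplification for this cell class.

Reciprocal inhibition is the same peak-normalized dual-exponential
conductance used for the motoneuron synapses, triggered whenever the
presynaptic voltage crosses 0 mV upward.  Its decay time constant tau_decay,
reversal E_Cl and conductance g_inh are the experimental knobs: slower decay
prolongs the inhibited phase of each half-center and slows the alternating
rhythm — strongly when E_Cl = −60 mV, only weakly when E_Cl is depolarized
to −50 mV, where the hyperpolarizing component of the IPSP has largely
collapsed.

Default cell parameters are calibrated so a single uncoupled cell bursts
with a period near 2 s, the scale of the drug-evoked locomotor rhythm
(1.88-2.01 s across genotypes); those biological periods are a calibration
scale only, not a validation target.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .rhythm import BurstSeries, phase_and_rayleigh
from .traces import Trace

__all__ = [
    "PacemakerCell", "HalfCenterNet", "RhythmResult",
    "build_halfcenter", "simulate_rhythm", "rhythm_period",
    "period_vs_taudecay", "burst_onsets_from_spikes",
]


@dataclass(frozen=True)
class PacemakerCell:
    """Single-compartment bursting interneuron (µS, nF, mV, ms, mM)."""

    c_m: float = 0.021          # nF
    g_leak: float = 0.0028      # µS
    e_leak: float = -58.0
    g_na: float = 0.028
    g_k: float = 0.0112
    e_na: float = 50.0
    e_k: float = -85.0
    g_nap: float = 0.0028
    # I_NaP slow inactivation.
    nap_theta_h: float = -48.0
    nap_sigma_h: float = 6.0
    nap_tauh_max: float = 10000.0   # ms
    # High-threshold Ca source for the K(Ca) pool.
    g_ca: float = 0.0002
    e_ca: float = 80.0
    ca_gain: float = 2e-4       # mM per (ms·nA) into the pool
    ca_tau: float = 300.0       # ms, pool clearance
    g_kca: float = 0.003
    kca_half: float = 0.001     # mM, Hill-2 half activation

    def __post_init__(self):
        for name in ("c_m", "g_leak", "g_na", "g_k"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("g_nap", "g_ca", "g_kca"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class HalfCenterNet:
    """Two reciprocally inhibiting pacemakers, optional follower MNs."""

    cell: PacemakerCell = PacemakerCell()
    g_inh: float = 0.04         # µS
    tau_rise: float = 0.3       # ms
    tau_decay: float = 20.0     # ms
    e_cl: float = -60.0         # mV
    followers: bool = False
    g_drive: float = 0.006      # µS, half-center -> follower excitation
    tau_rise_exc: float = 0.1
    tau_decay_exc: float = 10.0
    e_exc: float = 0.0

    def __post_init__(self):
        if self.g_inh < 0:
            raise ValueError("g_inh must be non-negative")
        if not 0 < self.tau_rise < self.tau_decay:
            raise ValueError("need 0 < tau_rise < tau_decay")


@dataclass(frozen=True)
class RhythmResult:
    """Rhythm summary of a half-center simulation."""

    period: float               # s (nan when not oscillating)
    period_sd: float
    phase: float                # left-right phase in [0, 1) (nan if n/a)
    oscillating: bool
    n_bursts: int

    def __post_init__(self):
        if self.oscillating and not self.period > 0:
            raise ValueError("oscillating result needs a positive period")


def _dual_exp_norm(tau_rise, tau_decay):
    tp = tau_rise * tau_decay / (tau_decay - tau_rise) \
        * np.log(tau_decay / tau_rise)
    return np.exp(-tp / tau_decay) - np.exp(-tp / tau_rise)


@njit(cache=True, fastmath=True)
def _cpg_kernel(nsteps, dt, p, g_inh, er_i, ed_i, w_inh, e_cl,
                followers, g_drive, er_e, ed_e, w_exc, e_exc,
                v_out):
    # p: parameter vector, see _param_vector for the layout.
    (c_m, g_leak, e_leak, g_na, g_k, e_na, e_k, g_nap,
     th_h, sg_h, tauh_max, g_ca, e_ca, ca_gain, ca_tau,
     g_kca, kca_half) = (p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7],
                         p[8], p[9], p[10], p[11], p[12], p[13], p[14],
                         p[15], p[16])
    ncell = 4 if followers else 2
    v = np.empty(ncell)
    n = np.empty(ncell)
    hp = np.empty(ncell)
    ca = np.empty(ncell)
    sa = np.zeros(ncell)   # synaptic rise state per *postsynaptic* cell
    sb = np.zeros(ncell)
    # Asymmetric initial conditions break the in-phase solution.
    v[0], v[1] = -60.0, -50.0
    hp[0], hp[1] = 0.7, 0.4
    for i in range(ncell):
        n[i] = 1.0 / (1.0 + np.exp(-(v[i] + 29.0) / 4.0))
        ca[i] = 0.0
        if i >= 2:
            v[i] = -65.0
            hp[i] = 0.5
    refrac = np.zeros(ncell)

    for step in range(nsteps):
        # Presynaptic threshold crossings trigger the antagonist's IPSC
        # (and the follower's EPSC) on the next step.
        fired0 = False
        fired1 = False
        for i in range(2):
            sa[i] *= er_i
            sb[i] *= ed_i
        if followers:
            for i in range(2, 4):
                sa[i] *= er_e
                sb[i] *= ed_e
        for i in range(ncell):
            vi = v[i]
            cell_is_pm = i < 2
            # Gates (exponential update).
            ninf = 1.0 / (1.0 + np.exp(-(vi + 29.0) / 4.0))
            taun = 10.0 / np.cosh((vi + 29.0) / 8.0)
            n[i] = ninf + (n[i] - ninf) * np.exp(-dt / taun)
            if cell_is_pm:
                hinf = 1.0 / (1.0 + np.exp((vi - th_h) / sg_h))
                tauh = tauh_max / np.cosh((vi - th_h) / (2.0 * sg_h))
                hp[i] = hinf + (hp[i] - hinf) * np.exp(-dt / tauh)
                cinf = 1.0 / (1.0 + np.exp(-(vi + 20.0) / 6.0))
                i_ca = g_ca * cinf * (vi - e_ca)
                drive = -ca_gain * i_ca
                if drive < 0.0:
                    drive = 0.0
                ca[i] += dt * (drive - ca[i] / ca_tau)
            minf = 1.0 / (1.0 + np.exp(-(vi + 34.0) / 5.0))
            mpinf = 1.0 / (1.0 + np.exp(-(vi + 40.0) / 6.0))
            g_na_t = g_na * minf * minf * minf * (1.0 - n[i])
            g_k_t = g_k * n[i] ** 4
            gtot = g_leak + g_na_t + g_k_t
            bb = c_m / dt * vi + g_leak * e_leak + g_na_t * e_na \
                + g_k_t * e_k
            if cell_is_pm:
                g_nap_t = g_nap * mpinf * hp[i]
                x = (ca[i] / kca_half) ** 2
                g_kca_t = g_kca * x / (1.0 + x)
                cinf = 1.0 / (1.0 + np.exp(-(vi + 20.0) / 6.0))
                g_ca_t = g_ca * cinf
                gtot += g_nap_t + g_kca_t + g_ca_t
                bb += g_nap_t * e_na + g_kca_t * e_k + g_ca_t * e_ca
                gs = g_inh * (sb[i] - sa[i]) * w_inh
                if gs < 0.0:
                    gs = 0.0
                gtot += gs
                bb += gs * e_cl
            else:
                gs = g_drive * (sb[i] - sa[i]) * w_exc
                if gs < 0.0:
                    gs = 0.0
                gtot += gs
                bb += gs * e_exc
            vnew = bb / (c_m / dt + gtot)
            if refrac[i] > 0.0:
                refrac[i] -= dt
            elif vi < 0.0 <= vnew and i == 0:
                fired0 = True
                refrac[i] = 2.0
            elif vi < 0.0 <= vnew and i == 1:
                fired1 = True
                refrac[i] = 2.0
            v[i] = vnew
        if fired0:
            sa[1] += 1.0
            sb[1] += 1.0
            if followers:
                sa[2] += 1.0
                sb[2] += 1.0
        if fired1:
            sa[0] += 1.0
            sb[0] += 1.0
            if followers:
                sa[3] += 1.0
                sb[3] += 1.0
        for i in range(ncell):
            v_out[step + 1, i] = v[i]
    return 0


def _param_vector(c: PacemakerCell) -> np.ndarray:
    return np.array([c.c_m, c.g_leak, c.e_leak, c.g_na, c.g_k, c.e_na,
                     c.e_k, c.g_nap, c.nap_theta_h, c.nap_sigma_h,
                     c.nap_tauh_max, c.g_ca, c.e_ca, c.ca_gain, c.ca_tau,
                     c.g_kca, c.kca_half])


def build_halfcenter(g_inh: float = 0.04, e_cl: float = -60.0,
                     tau_decay: float = 20.0, **kwargs) -> HalfCenterNet:
    """Assemble a half-center network; with g_inh = 0 the cells are uncoupled."""
    return HalfCenterNet(g_inh=g_inh, e_cl=e_cl, tau_decay=tau_decay,
                         **kwargs)


def simulate_rhythm(net: HalfCenterNet, tstop: float = 60.0,
                    dt_ms: float = 0.05) -> dict:
    """Integrate the network for ``tstop`` seconds; returns voltage traces.

    Deterministic: identical configurations give bit-identical traces.
    Keys ``left``/``right`` (and ``mn_left``/``mn_right`` with followers).
    """
    nsteps = int(round(tstop * 1e3 / dt_ms))
    ncell = 4 if net.followers else 2
    v_out = np.empty((nsteps + 1, ncell))
    v_out[0, :2] = (-60.0, -50.0)
    if net.followers:
        v_out[0, 2:] = -65.0
    _cpg_kernel(
        nsteps, dt_ms, _param_vector(net.cell),
        net.g_inh, np.exp(-dt_ms / net.tau_rise),
        np.exp(-dt_ms / net.tau_decay),
        1.0 / _dual_exp_norm(net.tau_rise, net.tau_decay), net.e_cl,
        net.followers, net.g_drive, np.exp(-dt_ms / net.tau_rise_exc),
        np.exp(-dt_ms / net.tau_decay_exc),
        1.0 / _dual_exp_norm(net.tau_rise_exc, net.tau_decay_exc),
        net.e_exc, v_out)
    if not np.all(np.isfinite(v_out)):
        raise FloatingPointError("CPG simulation diverged")
    dt_s = dt_ms * 1e-3
    names = ["left", "right", "mn_left", "mn_right"][:ncell]
    return {nm: Trace(dt_s, v_out[:, k], units="mV")
            for k, nm in enumerate(names)}


def burst_onsets_from_spikes(spikes: np.ndarray,
                             gap_s: float = 0.3) -> np.ndarray:
    """First spike of each burst: spikes separated by more than ``gap_s``."""
    if spikes.size == 0:
        return spikes
    brk = np.flatnonzero(np.diff(spikes) > gap_s)
    return np.concatenate(([spikes[0]], spikes[brk + 1]))


def rhythm_period(traces: dict, discard: int = 5,
                  gap_s: float = 0.3) -> RhythmResult:
    """Rhythm period and left-right phase from half-center voltage traces.

    Burst onsets are the first 0 mV crossings after a silence of
    ``gap_s``; the first ``discard`` bursts are dropped as transient.  The
    period is the mean inter-onset interval of the left cell; phase is the
    circular mean of right onsets within left cycles.  With fewer than
    three usable onsets the result is flagged non-oscillating.
    """
    from .model.mn import detect_spikes
    on = {}
    for side in ("left", "right"):
        spikes = detect_spikes(traces[side])
        onsets = burst_onsets_from_spikes(spikes, gap_s)
        on[side] = onsets[discard:] if onsets.size > discard else onsets[:0]
    left, right = on["left"], on["right"]
    if left.size < 3:
        return RhythmResult(period=np.nan, period_sd=np.nan, phase=np.nan,
                            oscillating=False, n_bursts=int(left.size))
    d = np.diff(left)
    period, sd = float(np.mean(d)), float(np.std(d, ddof=1))
    phase = np.nan
    if right.size >= 3:
        try:
            pr = phase_and_rayleigh(BurstSeries(left, side="left"),
                                    BurstSeries(right, side="right"))
            phase = pr.mean_phase
        except ValueError:
            phase = np.nan
    return RhythmResult(period=period, period_sd=sd, phase=phase,
                        oscillating=True, n_bursts=int(left.size))


def period_vs_taudecay(net_template: HalfCenterNet, taus,
                       tstop: float = 60.0, dt_ms: float = 0.05
                       ) -> list[RhythmResult]:
    """Rhythm results for each IPSC decay constant (ms) in ``taus``.

    Fixed g_inh and E_Cl from the template; non-oscillating points come
    back flagged rather than raising.
    """
    out = []
    for tau in taus:
        net = replace(net_template, tau_decay=float(tau))
        out.append(rhythm_period(simulate_rhythm(net, tstop=tstop,
                                                 dt_ms=dt_ms)))
    return out
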