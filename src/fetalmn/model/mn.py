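"""Canonical fetal (E17.5) motoneuron models and simulation protocols.

Two biophysical multi-compartment motoneurons are provided: a wild-type-like
(WT) cell and a SOD1-like (SOD) cell that is identical except for terminal
dendrites shortened to 60% of the WT length — the morphological difference
that makes the SOD cell more excitable.  The canonical morphology (soma,
symmetric dendritic tree, axon initial segment, long axon) is parameterized
in :class:`MNConfig`; its default dimensions were calibrated once so that
the WT model shows an input resistance of 120 MΩ and a spike threshold of
−48 mV, the two constraints the recorded cells impose, while the channel
densities are the printed reference values:

* leak everywhere, Rm = 21200 Ω·cm², E_leak = −73 mV;
* HH Na/K on the 750-segment axon (0.012 / 0.0036 S/cm²);
* dense HH Na/K (0.5 / 0.15 S/cm²) plus A-current (0.0033 S/cm²) on the
  initial segment;
* Ca-dependent K (I_C, 0.0025 S/cm²), high-threshold Ca (I_L, 8e-5 S/cm²)
  and the calcium pool (depth 0.17 µm, Michaelis-Menten pump kt = 2.5e-4
  mM/ms, kd = 1e-4 mM) on the soma.

Synaptic inputs are conductance-based dual exponentials delivered to the
soma; each event adds one peak-normalized transient, summing linearly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from ..traces import Trace
from . import channels as _ch
from .core import integrate
from .morphology import CompartmentTable, Section, flatten

__all__ = [
    "MNConfig", "MNModel", "SynapticTrain", "SimProtocol",
    "build_canonical_mn", "simulate", "measure_rin",
    "measure_spike_threshold", "detect_spikes", "firing_rate",
    "dual_exp_norm",
]


@dataclass(frozen=True)
class MNConfig:
    """Geometry, densities and kinetics of a canonical motoneuron.

    Lengths/diameters in µm, densities in S/cm², Ra in Ω·cm, cm in µF/cm².
    The morphometric defaults are the calibrated canonical tree; everything
    printed for the reference cells (Rm, E_leak, channel densities, calcium
    parameters, axon segment count) is fixed here at those values.
    """

    genotype: str = "WT"
    # Morphometry (calibrated; see docs/methods.md).
    soma_l: float = 24.0
    soma_diam: float = 24.0
    n_dend: int = 4
    dend_prim_l: float = 200.0
    dend_prim_diam: float = 2.0
    dend_term_l: float = 418.0
    dend_term_diam: float = 1.5
    ais_l: float = 50.0
    ais_diam: float = 4.0
    axon_l: float = 800.0
    axon_diam: float = 0.8
    axon_nseg: int = 750
    ra: float = 100.0
    cm: float = 1.0
    # Passive and active densities.
    rm: float = 21200.0          # Ω·cm²
    e_leak: float = -73.0
    gna_axon: float = 0.012
    gk_axon: float = 0.0036
    gna_ais: float = 0.5
    gk_ais: float = 0.15
    g_ia: float = 0.0033
    g_ic: float = 0.0025
    g_il: float = 8e-5
    e_na: float = _ch.ENA
    e_k: float = _ch.EK
    # I_C activation: saturating (Hill-4) calcium sensitivity and
    # activation time constant of the AHP conductance.
    kca_half: float = 1.5e-3     # mM
    kca_tau: float = 70.0        # ms
    # HH Na/K voltage frame (mV, positive = depolarized kinetics);
    # independent shifts keep Na available between slow spikes while the
    # initiation threshold stays near the measured −48 mV.
    vshift_m: float = 3.0
    vshift_h: float = 5.0
    vshift_n: float = 10.0
    # HH rate multiplier (1.0 = the classical rate set).
    hh_rate_scale: float = 1.0
    # I_L activation gate.
    l_vhalf: float = -20.0
    l_k: float = 6.0
    l_tau: float = 2.0
    # Calcium pool.
    ca_depth: float = 0.17       # µm
    ca_taur: float = 1e10        # ms
    ca_inf: float = 2e-4         # mM
    ca_kt: float = 2.5e-4        # mM/ms
    ca_kd: float = 1e-4          # mM
    ca_i0: float = 2.4e-4        # mM
    ca_o: float = 3.0            # mM
    # Unitary GABA/glycine conductance (µS); calibrated once on the WT
    # model: the smallest 0.001 µS grid value for which the 71 Hz,
    # tau_decay 25 ms, E −50 mV train silences the discharge while the
    # matching tau_decay 20 ms train remains inhibitory (below baseline).
    g_gaba_max: float = 0.046
    # SOD morphology: terminal dendrite scale factor.
    sod_terminal_scale: float = 0.6

    def __post_init__(self):
        if self.genotype not in ("WT", "SOD"):
            raise ValueError("genotype must be 'WT' or 'SOD'")
        for name in ("soma_l", "soma_diam", "dend_prim_l", "dend_term_l",
                     "ais_l", "axon_l", "rm", "ra", "cm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("gna_axon", "gk_axon", "gna_ais", "gk_ais", "g_ia",
                     "g_ic", "g_il", "g_gaba_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.axon_nseg < 1:
            raise ValueError("axon_nseg must be a positive integer")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "MNConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


class MNModel:
    """A built motoneuron: sections, compartment table, density arrays."""

    def __init__(self, config: MNConfig):
        self.config = config
        self.sections = _build_sections(config)
        self.comp: CompartmentTable = flatten(self.sections)
        self._arrays = _density_arrays(config, self.comp)

    @property
    def genotype(self) -> str:
        return self.config.genotype

    @property
    def soma_index(self) -> int:
        return self.comp.comp_index("soma", 0.5)

    def total_area_cm2(self) -> float:
        return float(np.sum(self.comp.area_cm2))


def _build_sections(cfg: MNConfig) -> list[Section]:
    term_l = cfg.dend_term_l
    if cfg.genotype == "SOD":
        term_l = cfg.dend_term_l * cfg.sod_terminal_scale
    secs = [Section("soma", cfg.soma_l, cfg.soma_diam, cfg.ra, cfg.cm,
                    nseg=1)]
    for k in range(cfg.n_dend):
        secs.append(Section(f"dend{k}_prim", cfg.dend_prim_l,
                            cfg.dend_prim_diam, cfg.ra, cfg.cm,
                            parent="soma", parent_pos=0.5))
        secs.append(Section(f"dend{k}_term", term_l, cfg.dend_term_diam,
                            cfg.ra, cfg.cm, parent=f"dend{k}_prim",
                            parent_pos=1.0))
    secs.append(Section("ais", cfg.ais_l, cfg.ais_diam, cfg.ra, cfg.cm,
                        parent="soma", parent_pos=0.0))
    secs.append(Section("axon", cfg.axon_l, cfg.axon_diam, cfg.ra, cfg.cm,
                        nseg=cfg.axon_nseg, parent="ais", parent_pos=1.0))
    return secs


def _density_arrays(cfg: MNConfig, comp: CompartmentTable) -> dict:
    n = comp.n
    area = comp.area_cm2
    to_abs = area * 1e6          # S/cm² -> µS
    gl = (1.0 / cfg.rm) * to_abs
    gna = np.zeros(n)
    gk = np.zeros(n)
    gia = np.zeros(n)
    gic = np.zeros(n)
    gil = np.zeros(n)
    ca_gain = np.zeros(n)

    ais = comp.section_mask("ais")
    axon = comp.section_mask("axon")
    soma = comp.section_mask("soma")
    gna[ais] = cfg.gna_ais * to_abs[ais]
    gk[ais] = cfg.gk_ais * to_abs[ais]
    gia[ais] = cfg.g_ia * to_abs[ais]
    gna[axon] = cfg.gna_axon * to_abs[axon]
    gk[axon] = cfg.gk_axon * to_abs[axon]
    gic[soma] = cfg.g_ic * to_abs[soma]
    gil[soma] = cfg.g_il * to_abs[soma]
    # mM per (ms·nA): shell of `depth` µm under the somatic membrane.
    ca_gain[soma] = 1e-2 / (2 * 96485.332 * area[soma] * cfg.ca_depth)

    return {
        "parent": comp.parent, "g_ax": comp.g_axial, "cm": comp.cm_nF,
        "gl": gl, "el": cfg.e_leak,
        "gna": gna, "gk": gk, "gia": gia, "gic": gic, "gil": gil,
        "ca_gain": ca_gain, "kt": cfg.ca_kt, "kd": cfg.ca_kd,
        "ca0": cfg.ca_i0, "cainf": cfg.ca_inf, "taur": cfg.ca_taur,
        "cao": cfg.ca_o, "kc": cfg.kca_half, "tau_o": cfg.kca_tau,
        "ena": cfg.e_na, "ek": cfg.e_k,
    }


def build_canonical_mn(genotype: str = "WT", **overrides) -> MNModel:
    """The canonical WT-like or SOD-like motoneuron model.

    ``overrides`` replace any :class:`MNConfig` field; invalid combinations
    raise the config's validation errors.
    """
    cfg = MNConfig(genotype=genotype, **overrides)
    return MNModel(cfg)


# ---------------------------------------------------------------------------
# Protocols and simulation


def dual_exp_norm(tau_rise: float, tau_decay: float) -> float:
    """Peak value of ``exp(-t/tau_decay) - exp(-t/tau_rise)`` (< 1)."""
    if not 0 < tau_rise < tau_decay:
        raise ValueError("need 0 < tau_rise < tau_decay")
    tp = tau_rise * tau_decay / (tau_decay - tau_rise) \
        * np.log(tau_decay / tau_rise)
    return float(np.exp(-tp / tau_decay) - np.exp(-tp / tau_rise))


@dataclass(frozen=True)
class SynapticTrain:
    """Event-timed dual-exponential conductance on one section.

    ``event_times_ms`` lists onset times; each event contributes a
    peak-normalized transient of amplitude ``g_max`` µS reversing at
    ``e_rev`` mV.
    """

    event_times_ms: tuple
    tau_rise: float = 0.3     # ms
    tau_decay: float = 20.0   # ms
    e_rev: float = -50.0      # mV
    g_max: float = 0.003      # µS
    section: str = "soma"
    x: float = 0.5

    def __post_init__(self):
        if not 0 < self.tau_rise < self.tau_decay:
            raise ValueError("need 0 < tau_rise < tau_decay")

    @classmethod
    def periodic(cls, freq_hz: float, onset_ms: float, duration_ms: float,
                 **kwargs) -> "SynapticTrain":
        """Constant-interval train at ``freq_hz`` starting at ``onset_ms``."""
        if freq_hz <= 0:
            return cls(event_times_ms=(), **kwargs)
        period = 1000.0 / freq_hz
        times = tuple(np.arange(onset_ms, onset_ms + duration_ms, period))
        return cls(event_times_ms=times, **kwargs)


@dataclass(frozen=True)
class SimProtocol:
    """What to do to the cell: current injections and synaptic trains.

    ``injections`` is a list of (t0_ms, t1_ms, i0_pA, i1_pA) linear current
    segments applied at the soma (a step has i0 = i1); ``synapses`` a list
    of :class:`SynapticTrain`.
    """

    tstop_ms: float
    dt_ms: float = 0.025
    injections: tuple = ()
    synapses: tuple = ()
    record: tuple = ("soma",)

    def __post_init__(self):
        if not self.dt_ms > 0:
            raise ValueError("dt must be positive")
        if not self.tstop_ms > 0:
            raise ValueError("tstop must be positive")


def _injection_waveform(protocol: SimProtocol, nsteps: int) -> np.ndarray:
    t = np.arange(nsteps) * protocol.dt_ms
    inj = np.zeros(nsteps)
    for t0, t1, i0, i1 in protocol.injections:
        m = (t >= t0) & (t < t1)
        if t1 > t0:
            inj[m] += (i0 + (i1 - i0) * (t[m] - t0) / (t1 - t0)) * 1e-3
        # pA -> nA
    return inj


def simulate(model: MNModel, protocol: SimProtocol) -> dict:
    """Integrate the model under a protocol; returns recorded traces.

    The result maps each recorded section name to a :class:`Trace` of the
    somatic-center voltage of that section (mV, time base in seconds), plus
    ``"g_syn"`` (total synaptic conductance, µS, exposed as a generic
    trace) and ``"ca"`` (somatic pool calcium, mM, raw ndarray).
    """
    dt = protocol.dt_ms
    nsteps = int(round(protocol.tstop_ms / dt))
    cfg = model.config
    tables = _ch.build_gate_tables(dt, cfg.l_vhalf, cfg.l_k, cfg.l_tau,
                                   cfg.vshift_m, cfg.vshift_h, cfg.vshift_n,
                                   cfg.hh_rate_scale)

    syn_comp, syn_gw, syn_er, syn_ed, syn_e = [], [], [], [], []
    ev = []     # (step, syn index, weight)
    for si, syn in enumerate(protocol.synapses):
        syn_comp.append(model.comp.comp_index(syn.section, syn.x))
        syn_gw.append(syn.g_max / dual_exp_norm(syn.tau_rise, syn.tau_decay))
        syn_er.append(np.exp(-dt / syn.tau_rise))
        syn_ed.append(np.exp(-dt / syn.tau_decay))
        syn_e.append(syn.e_rev)
        for t_ev in syn.event_times_ms:
            step = int(round(t_ev / dt))
            if 0 <= step < nsteps:
                ev.append((step, si, 1.0))
    ev.sort()
    synapses = {
        "comp": np.asarray(syn_comp, dtype=np.int32),
        "gw": np.asarray(syn_gw, dtype=float),
        "er": np.asarray(syn_er, dtype=float),
        "ed": np.asarray(syn_ed, dtype=float),
        "e": np.asarray(syn_e, dtype=float),
        "ev_step": np.asarray([e[0] for e in ev], dtype=np.int64),
        "ev_syn": np.asarray([e[1] for e in ev], dtype=np.int32),
        "ev_w": np.asarray([e[2] for e in ev], dtype=float),
    }
    injection = {"comp": model.soma_index,
                 "waveform": _injection_waveform(protocol, nsteps)}
    rec = [model.comp.comp_index(name, 0.5) for name in protocol.record]
    out = integrate(nsteps, dt, model._arrays, tables, synapses, injection,
                    rec)
    dt_s = dt * 1e-3
    result = {}
    for k, name in enumerate(protocol.record):
        result[name] = Trace(dt_s, out["v"][:, k], units="mV")
    result["g_syn"] = out["g_syn"]
    result["ca"] = out["ca"]
    return result


# ---------------------------------------------------------------------------
# Measurements


def detect_spikes(v: Trace, crossing: float = 0.0,
                  refractory_ms: float = 1.0) -> np.ndarray:
    """Spike times (s): upward crossings of ``crossing`` mV with refractory."""
    x = v.samples
    up = np.flatnonzero((x[:-1] < crossing) & (x[1:] >= crossing))
    if up.size == 0:
        return np.empty(0)
    times = v.t0 + (up + 1) * v.dt
    ref = refractory_ms * 1e-3
    keep = [times[0]]
    for t in times[1:]:
        if t - keep[-1] >= ref:
            keep.append(t)
    return np.asarray(keep)


def firing_rate(spikes: np.ndarray, window: tuple[float, float]) -> float:
    """Mean spike rate (Hz) inside the half-open window [t0, t1) seconds."""
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("window must have positive length")
    n = int(np.sum((spikes >= t0) & (spikes < t1)))
    return n / (t1 - t0)


def measure_rin(model: MNModel, step_pa: float = -10.0,
                settle_ms: float = 1000.0, step_ms: float = 1000.0) -> float:
    """Somatic input resistance (MΩ) from a small hyperpolarizing step.

    The cell rests for ``settle_ms``, then receives ``step_pa`` at the soma;
    Rin = ΔV_steady / ΔI from the last 10% of each epoch.  Raises if the
    baseline has not settled (drift > 0.1 mV over the read-out window).
    """
    prot = SimProtocol(tstop_ms=settle_ms + step_ms,
                       injections=((settle_ms, settle_ms + step_ms,
                                    step_pa, step_pa),))
    v = simulate(model, prot)["soma"]
    read = 0.1
    i0 = v.index_at((settle_ms * (1 - read)) * 1e-3)
    i1 = v.index_at(settle_ms * 1e-3)
    base_seg = v.samples[i0:i1]
    if np.ptp(base_seg) > 0.1:
        raise RuntimeError("baseline not settled before the test step")
    v_base = float(np.mean(base_seg))
    j0 = v.index_at((settle_ms + step_ms * (1 - read)) * 1e-3)
    v_step = float(np.mean(v.samples[j0:]))
    return (v_step - v_base) / (step_pa * 1e-3)   # mV / nA = MΩ


def measure_spike_threshold(model: MNModel, ramp_pa: float = 400.0,
                            ramp_ms: float = 2000.0,
                            dvdt_crit: float = 10.0) -> float:
    """Spike threshold (mV): somatic V at the first dV/dt crossing.

    A slow 0 → ``ramp_pa`` ramp over ``ramp_ms`` depolarizes the cell after
    a 500 ms rest; the threshold is the somatic voltage at the first sample
    where dV/dt reaches ``dvdt_crit`` mV/ms.  Raises if the cell never
    spikes.
    """
    settle = 500.0
    prot = SimProtocol(tstop_ms=settle + ramp_ms,
                       injections=((settle, settle + ramp_ms, 0.0,
                                    ramp_pa),))
    v = simulate(model, prot)["soma"]
    dvdt = np.gradient(v.samples, v.dt * 1e3)   # mV/ms
    start = v.index_at(settle * 1e-3)
    idx = np.flatnonzero(dvdt[start:] >= dvdt_crit)
    if idx.size == 0:
        raise RuntimeError("no spike during the threshold ramp")
    return float(v.samples[start + idx[0]])
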