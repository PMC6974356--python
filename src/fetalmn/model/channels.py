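"""Voltage-gated channel kinetics for the motoneuron model.

Gate dynamics are first order, dx/dt = (x_inf(V) − x)/tau_x(V), advanced
with the exact exponential update x += (x_inf − x)(1 − exp(−dt/tau_x)),
which is unconditionally stable.  For speed the integrator consumes lookup
tables of x_inf(V) and exp(−dt/tau_x(V)) on a fine voltage grid.

Channel set
-----------
* Hodgkin-Huxley Na (m³h) and delayed-rectifier K (n⁴) on the axon and the
  axon initial segment — the classic squid rate functions at their
  conventional resting frame (E_Na = +50 mV, E_K = −77 mV).
* A-type transient K current (a³b, Connor-Stevens kinetics) on the initial
  segment, where it delays spike initiation.
* High-threshold (L-type) Ca current on the soma, one activation gate with
  a sigmoid steady state, ohmic driving force with E_Ca from the somatic
  calcium pool via the Nernst relation.
* Ca-dependent K current (I_K(Ca) / I_C) on the soma: a saturating Hill
  function of the pool calcium drives a first-order activation variable
  with a fixed time constant, producing the medium AHP that sets the slow
  repetitive firing range.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "VMIN", "VMAX", "VSTEP", "build_gate_tables",
    "ENA", "EK",
]

ENA = 50.0    # mV
EK = -77.0    # mV

VMIN, VMAX, VSTEP = -120.0, 80.0, 0.05


def _safe_expm1_ratio(x):
    """x / (exp(x) - 1), continuous through x = 0."""
    x = np.asarray(x, dtype=float)
    out = np.where(np.abs(x) < 1e-7, 1.0 - x / 2,
                   x / np.expm1(np.where(np.abs(x) < 1e-7, 1.0, x)))
    return out


# --- Hodgkin-Huxley Na/K rate functions (ms^-1, V in mV) ---

def alpha_m(v):
    return _safe_expm1_ratio(-(v + 40.0) / 10.0)  # = 0.1(v+40)/(1-exp(-(v+40)/10))


def beta_m(v):
    return 4.0 * np.exp(-(v + 65.0) / 18.0)


def alpha_h(v):
    return 0.07 * np.exp(-(v + 65.0) / 20.0)


def beta_h(v):
    return 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))


def alpha_n(v):
    return 0.1 * _safe_expm1_ratio(-(v + 55.0) / 10.0)


def beta_n(v):
    return 0.125 * np.exp(-(v + 65.0) / 80.0)


# --- Connor-Stevens A-current kinetics ---

def a_inf(v):
    num = 0.0761 * np.exp((v + 94.22) / 31.84)
    den = 1.0 + np.exp((v + 1.17) / 28.93)
    return (num / den) ** (1.0 / 3.0)


def tau_a(v):
    return 0.3632 + 1.158 / (1.0 + np.exp((v + 55.96) / 20.12))


def b_inf(v):
    return (1.0 / (1.0 + np.exp((v + 53.3) / 14.54))) ** 4


def tau_b(v):
    return 1.24 + 2.678 / (1.0 + np.exp((v + 50.0) / 16.027))


# --- High-threshold Ca activation (one gate) ---

def l_inf(v, vhalf=-20.0, k=6.0):
    return 1.0 / (1.0 + np.exp(-(v - vhalf) / k))


def tau_l(v, tau=2.0):
    return np.full_like(np.asarray(v, dtype=float), tau)


def build_gate_tables(dt_ms: float, l_vhalf: float = -20.0,
                      l_k: float = 6.0, l_tau: float = 2.0,
                      vshift_m: float = 0.0, vshift_h: float = 0.0,
                      vshift_n: float = 0.0, hh_rate_scale: float = 1.0):
    """Lookup tables (x_inf, exp(−dt/tau)) for all voltage-dependent gates.

    Returns a dict of (inf, factor) float64 array pairs on the grid
    ``VMIN:VMAX:VSTEP``, for gates m, h, n, a, b, l.  The ``vshift_*``
    arguments translate each HH rate pair along the voltage axis
    (positive = depolarized).  Independent shifts let Na stay available at
    the depolarized operating point of a slowly firing cell while spike
    initiation still occurs near the measured threshold — the standard
    adaptation when moving the squid rate functions to a motoneuron.
    ``hh_rate_scale`` multiplies all HH rates; the default model uses the
    30 °C value (Q10 = 3 relative to the 6.3 °C reference frame), making
    gate relaxation fast next to every synaptic and membrane time scale.
    """
    v = np.arange(VMIN, VMAX + VSTEP / 2, VSTEP)
    tables = {}
    shifts = {"m": vshift_m, "h": vshift_h, "n": vshift_n}
    for name, (am, bm) in {"m": (alpha_m, beta_m), "h": (alpha_h, beta_h),
                           "n": (alpha_n, beta_n)}.items():
        vs = v - shifts[name]
        a, b = am(vs), bm(vs)
        tau = 1.0 / (a + b) / hh_rate_scale
        tables[name] = ((a * tau).astype(float),
                        np.exp(-dt_ms / tau))
    tables["a"] = (a_inf(v), np.exp(-dt_ms / tau_a(v)))
    tables["b"] = (b_inf(v), np.exp(-dt_ms / tau_b(v)))
    tables["l"] = (l_inf(v, l_vhalf, l_k),
                   np.exp(-dt_ms / tau_l(v, l_tau)))
    return tables
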