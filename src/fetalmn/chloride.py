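"""Chloride physiology arithmetic for fetal motoneuron recordings.

GABA_A- and glycine-receptor channels pass chloride, so the reversal
potential of inhibitory currents (E_GABAAR, here interchangeable with E_Cl
under the pure-chloride assumption) follows the Nernst relation

    E_Cl = -(RT/F) * ln([Cl-]_o / [Cl-]_i)  =  (RT/F) * ln([Cl-]_i / [Cl-]_o)

for a monovalent anion (z = -1).  At 30 °C, RT/F ≈ 26.12 mV.  This module
implements the measurement chain built on that relation:

* Nernst conversion between E_Cl and intracellular chloride, both ways;
* the driving force of GABAergic currents, reported with the depolarizing
  convention DF = E_GABAAR − E_m so that depolarized reversal gives a
  positive number;
* E_GABAAR from a linear fit of an agonist-evoked I/V series (zero-current
  crossing);
* E_Cl from a voltage-ramp subtraction protocol: the agonist-sensitive
  current (agonist ramp minus control ramp) reverses at E_Cl.

Defaults describe the recording conditions these methods were designed for:
extracellular chloride 123.5 mM (the summed chloride content of the aCSF:
114.5 from NaCl + 3 from KCl + 4 from 2 mM CaCl2 + 2 from 1 mM MgCl2) and
30 °C.  Recordings may carry a liquid-junction
potential; correcting for it (3.3 mV in the reference chain) is left to the
caller as a preprocessing step and is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import constants, stats

__all__ = [
    "ChlorideContext", "IVSeries", "RampPair",
    "nernst_ecl", "cl_in_from_ecl", "driving_force",
    "fit_reversal", "ramp_subtraction_ecl",
    "NoReversalError", "AmbiguousCrossingError",
    "DEFAULT_CL_OUT_MM", "DEFAULT_TEMPERATURE_K", "JUNCTION_POTENTIAL_MV",
]

#: Extracellular chloride of the standard aCSF, mM (114.5 NaCl + 3 KCl
#: + 2 CaCl2 + 1 MgCl2 -> 114.5 + 3 + 4 + 2 = 123.5 mM Cl-).
DEFAULT_CL_OUT_MM = 123.5
#: Bath temperature, K (recordings at 30 °C).
DEFAULT_TEMPERATURE_K = 303.15
#: Liquid-junction potential of the reference recording chain, mV.  Apply
#: to voltages caller-side when desired; nothing here applies it implicitly.
JUNCTION_POTENTIAL_MV = 3.3


class NoReversalError(ValueError):
    """The I/V data or ramp difference has no usable zero crossing."""


class AmbiguousCrossingError(ValueError):
    """The ramp difference crosses zero more than once."""

    def __init__(self, crossings_mv):
        self.crossings_mv = list(crossings_mv)
        super().__init__(
            f"difference current crosses zero {len(self.crossings_mv)} times "
            f"(at {self.crossings_mv} mV); expected exactly one crossing")


@dataclass(frozen=True)
class ChlorideContext:
    """Bath conditions entering the Nernst relation."""

    cl_out: float = DEFAULT_CL_OUT_MM       # mM
    temperature: float = DEFAULT_TEMPERATURE_K  # K

    def __post_init__(self):
        if not self.cl_out > 0:
            raise ValueError("cl_out must be positive")
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")

    @property
    def rt_over_f(self) -> float:
        """Thermal voltage RT/F in mV."""
        return constants.R * self.temperature / constants.value(
            "Faraday constant") * 1e3


@dataclass(frozen=True)
class IVSeries:
    """Peak agonist-evoked current at a series of holding potentials."""

    holdings: np.ndarray  # mV
    currents: np.ndarray  # pA

    def __post_init__(self):
        object.__setattr__(self, "holdings",
                           np.asarray(self.holdings, dtype=float))
        object.__setattr__(self, "currents",
                           np.asarray(self.currents, dtype=float))
        if self.holdings.size != self.currents.size:
            raise ValueError("holdings and currents must have equal length")
        if self.holdings.size < 2:
            raise ValueError("need at least two I/V points")
        if np.any(np.diff(self.holdings) <= 0):
            raise ValueError("holding potentials must be strictly increasing")


@dataclass(frozen=True)
class RampPair:
    """Control and agonist voltage-ramp currents on a common voltage grid."""

    voltages: np.ndarray        # mV, monotone increasing command
    control_current: np.ndarray  # pA
    iso_current: np.ndarray      # pA, in the presence of the agonist

    def __post_init__(self):
        for name in ("voltages", "control_current", "iso_current"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))
        if not (self.voltages.size == self.control_current.size
                == self.iso_current.size):
            raise ValueError("ramp arrays must have equal length")
        if np.any(np.diff(self.voltages) <= 0):
            raise ValueError("ramp voltage must be monotone increasing")


def nernst_ecl(cl_in: float, ctx: ChlorideContext = ChlorideContext()) -> float:
    """Chloride Nernst potential in mV from intracellular chloride (mM).

    ``E_Cl = (RT/F) ln(cl_in / cl_out)`` for z = −1; strictly increasing in
    ``cl_in`` and zero when the two concentrations are equal.
    """
    cl_in = np.asarray(cl_in, dtype=float)
    if np.any(cl_in <= 0):
        raise ValueError("cl_in must be positive")
    out = ctx.rt_over_f * np.log(cl_in / ctx.cl_out)
    return float(out) if out.ndim == 0 else out


def cl_in_from_ecl(ecl: float, ctx: ChlorideContext = ChlorideContext()) -> float:
    """Intracellular chloride (mM) from a chloride reversal potential (mV).

    Exact inverse of :func:`nernst_ecl`; every real potential maps to a
    positive concentration.
    """
    ecl = np.asarray(ecl, dtype=float)
    out = ctx.cl_out * np.exp(ecl / ctx.rt_over_f)
    return float(out) if out.ndim == 0 else out


def driving_force(e_gaba: float, e_m: float) -> float:
    """Driving force of GABA/glycine currents, ``e_gaba − e_m`` in mV.

    Positive for depolarizing GABA (reversal above rest); this sign
    convention makes the reported fetal values positive, e.g.
    driving_force(−50.5, −73.1) = 22.6 mV.
    """
    return e_gaba - e_m


def fit_reversal(iv: IVSeries, slope_tol: float = 1e-12) -> float:
    """E_GABAAR (mV) as the zero-current crossing of a linear I/V fit.

    Ordinary least squares through (holding, current); returns
    −intercept/slope.  Raises :class:`NoReversalError` when the fitted slope
    is smaller than ``slope_tol`` pA/mV in magnitude (no defined crossing).
    """
    res = stats.linregress(iv.holdings, iv.currents)
    if abs(res.slope) <= slope_tol:
        raise NoReversalError("I/V slope is zero within tolerance; "
                              "no reversal potential defined")
    return float(-res.intercept / res.slope)


def ramp_subtraction_ecl(ramp: RampPair) -> float:
    """E_Cl (mV) from ramp subtraction: zero crossing of (agonist − control).

    The agonist-sensitive current is the pointwise difference of the two
    ramps; its unique sign change, linearly interpolated between samples, is
    the chloride reversal.  Adding any common current to both ramps leaves
    the result unchanged.  Raises :class:`NoReversalError` if the difference
    never changes sign and :class:`AmbiguousCrossingError` (listing every
    crossing) if it changes sign more than once.
    """
    diff = ramp.iso_current - ramp.control_current
    sign = np.sign(diff)
    # Treat exact zeros as crossings at the sample voltage.
    crossings = []
    nz = np.nonzero(sign)[0]
    if nz.size == 0:
        raise NoReversalError("difference current is identically zero")
    # Indices where consecutive nonzero signs differ.
    for a, b in zip(nz[:-1], nz[1:]):
        if sign[a] != sign[b]:
            v0, v1 = ramp.voltages[a], ramp.voltages[b]
            d0, d1 = diff[a], diff[b]
            crossings.append(v0 + (v1 - v0) * (-d0) / (d1 - d0))
    # Samples that are exactly zero count as crossings themselves.
    zeros = np.nonzero(sign == 0)[0]
    for i in zeros:
        # Only an isolated interior zero between opposite signs, or a zero
        # bounded by same signs, matters; report the voltage either way.
        crossings.append(float(ramp.voltages[i]))
    crossings = sorted(set(round(c, 12) for c in crossings))
    if len(crossings) == 0:
        raise NoReversalError("difference current does not change sign")
    if len(crossings) > 1:
        raise AmbiguousCrossingError(crossings)
    return float(crossings[0])
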