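"""Uniformly sampled time-series container shared by all analysis stages.

A :class:`Trace` is the in-memory form of every recording this package
consumes or produces: voltage-clamp current (pA), current-clamp voltage (mV),
or a rectified activity envelope (Hz treated as a generic signal).  On disk a
trace is a two-column CSV ``time_s,value`` with the units recorded in a
``# units:`` comment line, readable and writable with :func:`read_trace_csv`
and :func:`write_trace_csv`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Trace", "read_trace_csv", "write_trace_csv"]

_ALLOWED_UNITS = ("pA", "mV", "Hz")


@dataclass
class Trace:
    """A uniformly sampled signal.

    Parameters
    ----------
    dt : float
        Sample interval in seconds (> 0).
    samples : ndarray
        Signal values; at least two finite samples.
    t0 : float
        Time of the first sample in seconds.
    units : str
        One of ``pA``, ``mV`` or ``Hz``.
    """

    dt: float
    samples: np.ndarray
    t0: float = 0.0
    units: str = "pA"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("trace needs at least two samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")
        if self.units not in _ALLOWED_UNITS:
            raise ValueError(f"units must be one of {_ALLOWED_UNITS}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Span from first to last sample, in seconds."""
        return (self.n - 1) * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / self.dt

    def index_at(self, t: float) -> int:
        """Nearest sample index for time ``t`` (seconds, clipped to range)."""
        i = int(round((t - self.t0) / self.dt))
        return min(max(i, 0), self.n - 1)

    def slice(self, t_start: float, t_stop: float) -> "Trace":
        """Sub-trace covering [t_start, t_stop] (seconds)."""
        i0 = self.index_at(t_start)
        i1 = self.index_at(t_stop) + 1
        if i1 - i0 < 2:
            raise ValueError("requested slice contains fewer than two samples")
        return Trace(self.dt, self.samples[i0:i1].copy(),
                     t0=self.t0 + i0 * self.dt, units=self.units,
                     meta=dict(self.meta))


def read_trace_csv(path) -> Trace:
    """Read a two-column ``time_s,value`` CSV with a ``# units:`` header."""
    units = "pA"
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if "units:" in line:
                    units = line.split("units:")[1].strip()
            else:
                break
    df = pd.read_csv(path, comment="#")
    t = df.iloc[:, 0].to_numpy(float)
    if t.size < 2:
        raise ValueError("trace file has fewer than two rows")
    dts = np.diff(t)
    dt = float(np.median(dts))
    if not np.allclose(dts, dt, rtol=1e-6, atol=1e-9):
        raise ValueError("trace file is not uniformly sampled")
    return Trace(dt, df.iloc[:, 1].to_numpy(float), t0=float(t[0]), units=units)


def write_trace_csv(trace: Trace, path, value_label: str | None = None) -> None:
    label = value_label or {"pA": "current_pA", "mV": "voltage_mV",
                            "Hz": "rate_Hz"}[trace.units]
    with open(path, "w") as fh:
        fh.write(f"# units: {trace.units}\n")
        fh.write(f"time_s,{label}\n")
        for t, v in zip(trace.times, trace.samples):
            fh.write(f"{t:.9g},{v:.9g}\n")
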