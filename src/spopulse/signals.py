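"""Synthetic Spo0A~P input signals.

Every input class consumed by the network models is built here:

* ``cosine_signal`` — zero-minimum cosine oscillations, value(t) =
  amplitude * cos(2*pi*t/T) + amplitude, so the time-mean equals the
  amplitude and the minimum is exactly 0.
* ``square_signal`` — square pulse trains with independently scheduled
  ON/OFF plateau durations.
* ``per_cycle_constant`` — replaces a signal, cycle by cycle, with its
  per-cycle mean, max or min (the "constant input" comparators).
* ``natural_pulse_signal`` — the once-per-cell-cycle Spo0A~P pulse produced
  by the deterministic phosphorelay model (see :mod:`spopulse.phosphorelay`).

Signals carry a uniform time grid in hours and non-negative values in µM
(deterministic use) or molecules (stochastic use).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .cellcycle import CycleTiming, timing_from_growth

__all__ = [
    "Signal",
    "CosineSpec",
    "SquarePulseSpec",
    "cosine_signal",
    "square_signal",
    "per_cycle_constant",
    "natural_pulse_signal",
]


@dataclass
class Signal:
    """A time-resolved Spo0A~P input on a uniform grid.

    Attributes
    ----------
    times : ndarray
        Strictly increasing, uniformly spaced time grid (h).
    values : ndarray
        Non-negative signal values at each time.
    units : str
        "uM" or "molecules".
    """

    times: np.ndarray
    values: np.ndarray
    units: str = "uM"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("signal needs a 1-D grid with at least two points")
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same shape")
        dts = np.diff(self.times)
        if np.any(dts <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-12):
            raise ValueError("time grid must be uniform")
        if np.any(self.values < -1e-12):
            raise ValueError("signal values must be non-negative")
        self.values = np.maximum(self.values, 0.0)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def interpolator(self) -> Callable[[float], float]:
        """Linear interpolant clamped to the end values outside the grid."""
        t, v = self.times, self.values
        return lambda x: float(np.interp(x, t, v))

    def mean(self) -> float:
        """Time-average over the grid (trapezoid rule)."""
        return float(np.trapezoid(self.values, self.times) / self.duration)

    def shifted(self, t0: float) -> "Signal":
        return Signal(self.times - self.times[0] + t0, self.values.copy(), self.units)

    def to_csv(self, path: str | Path) -> None:
        """Write two-column CSV (time_h, value) with a JSON units sidecar."""
        path = Path(path)
        arr = np.column_stack([self.times, self.values])
        np.savetxt(path, arr, delimiter=",", header="time_h,value", comments="")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({"units": self.units, "dt_h": self.dt}))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Signal":
        path = Path(path)
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        units = "uM"
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            units = json.loads(sidecar.read_text()).get("units", "uM")
        return cls(arr[:, 0], arr[:, 1], units)


@dataclass(frozen=True)
class CosineSpec:
    """Zero-minimum cosine oscillation: amplitude*cos(2*pi*t/T) + offset.

    The offset equals the amplitude so the signal minimum is 0 and the
    time-mean over full periods equals the amplitude.
    """

    amplitude: float
    period: float

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    @property
    def freq(self) -> float:
        """Angular frequency 2*pi/T in 1/h."""
        return 2.0 * math.pi / self.period

    @property
    def offset(self) -> float:
        return self.amplitude


@dataclass(frozen=True)
class SquarePulseSpec:
    """Square pulse train with per-cycle ON and OFF plateau durations."""

    high: float
    low: float
    on_durations: tuple[float, ...]
    off_durations: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.on_durations) != len(self.off_durations):
            raise ValueError("on_durations and off_durations must have equal length")
        if len(self.on_durations) == 0:
            raise ValueError("need at least one cycle")
        if any(d <= 0 for d in self.on_durations + self.off_durations):
            raise ValueError("all durations must be positive")
        if self.high < 0 or self.low < 0:
            raise ValueError("levels must be non-negative")


def cosine_signal(spec: CosineSpec, duration: float, dt: float = 0.005) -> Signal:
    """Sample a zero-minimum cosine oscillation on a uniform grid.

    Requires ``duration >= period`` and ``dt <= period/50`` so that each
    oscillation is resolved.
    """
    if duration < spec.period:
        raise ValueError("duration must cover at least one period")
    if dt > spec.period / 50.0:
        raise ValueError(
            f"dt = {dt} too coarse for period {spec.period} (need dt <= T/50)"
        )
    n = int(round(duration / dt))
    times = np.arange(n + 1) * dt
    values = spec.amplitude * np.cos(spec.freq * times) + spec.offset
    return Signal(times, values)


def square_signal(spec: SquarePulseSpec, dt: float = 0.005) -> Signal:
    """Alternating high/low plateaus with the scheduled durations, ON first."""
    edges = [0.0]
    levels: list[float] = []
    for on_d, off_d in zip(spec.on_durations, spec.off_durations):
        edges.append(edges[-1] + on_d)
        levels.append(spec.high)
        edges.append(edges[-1] + off_d)
        levels.append(spec.low)
    total = edges[-1]
    n = int(round(total / dt))
    times = np.arange(n + 1) * dt
    idx = np.clip(np.searchsorted(edges, times, side="right") - 1, 0, len(levels) - 1)
    values = np.asarray(levels)[idx]
    return Signal(times, values)


def per_cycle_constant(signal: Signal, boundaries: Sequence[float],
                       mode: str = "mean") -> Signal:
    """Replace a signal by its per-cycle constant (mean, max or min).

    Parameters
    ----------
    boundaries : sequence of float
        Cycle edge times (at least two), increasing, within the signal
        support.  Cycle i covers [boundaries[i], boundaries[i+1]).  Times
        before the first / after the last edge take the first / last
        cycle's constant.
    mode : {"mean", "max", "min"}
        Per-cycle statistic; "mean" is the time-average (trapezoid rule
        with interpolated edge values), preserving each cycle's integral.
    """
    if mode not in ("mean", "max", "min"):
        raise ValueError(f"mode must be mean, max or min, got {mode!r}")
    edges = np.asarray(sorted(boundaries), dtype=float)
    if edges.size < 2:
        raise ValueError("need at least two cycle boundaries")
    t0, t1 = signal.times[0], signal.times[-1]
    if edges[0] < t0 - 1e-9 or edges[-1] > t1 + 1e-9:
        raise ValueError("cycle boundaries must lie within the signal support")
    constants = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi - lo <= 0:
            raise ValueError("empty cycle between boundaries")
        inside = (signal.times > lo) & (signal.times < hi)
        ts = np.concatenate(([lo], signal.times[inside], [hi]))
        vs = np.concatenate((
            [np.interp(lo, signal.times, signal.values)],
            signal.values[inside],
            [np.interp(hi, signal.times, signal.values)],
        ))
        if mode == "mean":
            constants.append(np.trapezoid(vs, ts) / (hi - lo))
        elif mode == "max":
            constants.append(vs.max())
        else:
            constants.append(vs.min())
    idx = np.clip(np.searchsorted(edges, signal.times, side="right") - 1,
                  0, len(constants) - 1)
    return Signal(signal.times, np.asarray(constants)[idx], signal.units)


def natural_pulse_signal(g: float | None = None,
                         timing: CycleTiming | None = None,
                         n_cycles: int = 8,
                         params=None,
                         dt: float = 0.005,
                         discard_cycles: int = 3) -> Signal:
    """Spo0A~P natural pulsing produced by the phosphorelay model.

    Simulates the deterministic phosphorelay at the requested growth rate
    (or explicit :class:`CycleTiming`, e.g. with replication-period
    overrides) and returns the post-transient [0A~P] trace.  The pulse
    period equals the cell-cycle length; the trough falls in the DNA
    replication window and the overshoot after it.
    """
    from .phosphorelay import PhosphorelayParams, simulate_phosphorelay

    if timing is None:
        if g is None:
            raise ValueError("provide either g or timing")
        timing = timing_from_growth(g)
    if params is None:
        params = PhosphorelayParams.default()
    return simulate_phosphorelay(params, timing, n_cycles=n_cycles, dt=dt,
                                 discard_cycles=discard_cycles)
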