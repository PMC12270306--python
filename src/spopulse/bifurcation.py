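"""Steady-state structure and deactivation thresholds of the matrix network.

Under a constant Spo0A~P input the network is bistable above a threshold
concentration MOFF (matrix-ON and matrix-OFF steady states coexist) and
monostable OFF below it.  Under zero-minimum cosine oscillations the
threshold is defined on the oscillation *mean*: the smallest mean that
sustains the matrix-ON state over a long horizon.  The matched-period
analysis evaluates that threshold where the oscillation period equals the
cell-cycle length and summarises the curve with the power law

    MOFF(tau_cyc) = a * tau_cyc**b + c      [µM]

fitted by nonlinear least squares.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .biofilm_ode import (BiofilmParams, GrowthEffects, IDX_TAPA,
                          _on_seed, on_off_states, simulate_biofilm,
                          steady_state)
from .cellcycle import CycleTiming, timing_from_growth
from .phosphorelay import IntegrationError
from .signals import CosineSpec

__all__ = [
    "ThresholdCurve",
    "PowerLawFit",
    "constant_input_steady_states",
    "bistable_threshold_constant",
    "oscillatory_threshold",
    "matched_period_curve",
    "power_law_fit",
]


def _timing(g: float) -> CycleTiming:
    return timing_from_growth(g, allow_overlap=True)


@dataclass
class ThresholdCurve:
    """Deactivation thresholds along an abscissa (period, cycle length, g)."""

    abscissa: np.ndarray
    thresholds: np.ndarray
    abscissa_name: str = "tau_cyc_h"
    input_class: str = "cosine"

    def __post_init__(self) -> None:
        self.abscissa = np.asarray(self.abscissa, float)
        self.thresholds = np.asarray(self.thresholds, float)
        order = np.argsort(self.abscissa)
        self.abscissa = self.abscissa[order]
        self.thresholds = self.thresholds[order]
        if np.any(self.thresholds <= 0):
            raise ValueError("thresholds must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "abscissa_name": self.abscissa_name,
            "input_class": self.input_class,
            "abscissa": self.abscissa.tolist(),
            "thresholds_uM": self.thresholds.tolist(),
        }, indent=2))


@dataclass
class PowerLawFit:
    """Fit of MOFF = a*tau^b + c with coefficient of determination."""

    a: float
    b: float
    c: float
    r_squared: float

    def __call__(self, tau):
        return self.a * np.asarray(tau, float) ** self.b + self.c

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"a": self.a, "b": self.b, "c": self.c,
             "r_squared": self.r_squared}, indent=2))


def constant_input_steady_states(c0A: float, g: float,
                                 params: BiofilmParams | None = None,
                                 effects: GrowthEffects = GrowthEffects(),
                                 distinct_factor: float = 10.0):
    """Stable fixed points (TapA levels) under a constant input.

    Integrates to steady state from an OFF-like (empty) and an ON-like
    (SinR-sequestered) initial condition and reports the distinct stable
    states found, labelled 'OFF'/'ON' by TapA level.
    """
    if c0A < 0:
        raise ValueError("c0A must be non-negative")
    params = params or BiofilmParams.default()
    on, off = on_off_states(params, c0A, _timing(g), effects)
    t_on, t_off = on[IDX_TAPA], off[IDX_TAPA]
    if t_on > distinct_factor * t_off:
        return {"OFF": t_off, "ON": t_on}
    return {"OFF": t_off} if t_off < 1.0 else {"ON": t_off}


def bistable_threshold_constant(g: float,
                                params: BiofilmParams | None = None,
                                effects: GrowthEffects = GrowthEffects(),
                                lo: float = 0.0, hi: float = 2.0,
                                tol: float = 1e-3,
                                distinct_factor: float = 10.0) -> float:
    """MOFF under constant input: bisection on c0A for ON-branch survival.

    Returns the smallest constant [0A~P] (µM) at which the matrix-ON
    steady state still exists, to within ``tol``.

    Raises
    ------
    IntegrationError
        If the ON branch does not exist anywhere in [lo, hi] (e.g. the
        activation arm of the network is disabled), naming the range.
    """
    params = params or BiofilmParams.default()
    timing = _timing(g)
    off_ref = steady_state(params, 0.0, timing, None, effects)

    def on_survives(c: float) -> bool:
        try:
            on = steady_state(params, c, timing, _on_seed(), effects)
        except IntegrationError:
            return False
        return on[IDX_TAPA] > distinct_factor * off_ref[IDX_TAPA]

    if not on_survives(hi):
        raise IntegrationError(
            f"no matrix-ON state found for c0A in [{lo}, {hi}] µM at g={g}")
    if on_survives(lo):
        return lo
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if on_survives(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def oscillatory_threshold(period: float, g: float,
                          params: BiofilmParams | None = None,
                          effects: GrowthEffects = GrowthEffects(),
                          lo: float = 0.0, hi: float = 2.0,
                          tol: float = 1e-3,
                          distinct_factor: float = 10.0) -> float:
    """Deactivation threshold mean for a zero-minimum cosine input.

    The input is amplitude*cos(2*pi*t/T) + amplitude (mean = amplitude,
    minimum 0).  Bisection on the amplitude; ON survival is judged from an
    ON-initialised simulation over max(200 h, 25 periods), classifying the
    final full period's mean TapA against ``distinct_factor`` times the
    zero-input OFF level.  Returns the smallest sustaining mean (µM).
    """
    if period <= 0:
        raise ValueError("period must be positive")
    params = params or BiofilmParams.default()
    timing = _timing(g)
    horizon = max(200.0, 25.0 * period)
    off_ref = steady_state(params, 0.0, timing, None, effects)
    w = 2.0 * math.pi / period
    y_on = steady_state(params, 2.0, timing, _on_seed(), effects)

    def on_survives(mean: float) -> bool:
        inp = lambda t: mean * (1.0 + math.cos(w * t))
        ts, ys = simulate_biofilm(params, inp, timing, horizon, y_on, effects)
        sel = ts >= ts[-1] - period
        tap = float(np.trapezoid(ys[IDX_TAPA, sel], ts[sel]) /
                    (ts[sel][-1] - ts[sel][0]))
        return tap > distinct_factor * off_ref[IDX_TAPA]

    # expand the bracket if the threshold exceeds the initial guess
    while not on_survives(hi):
        hi *= 2.0
        if hi > 64.0:
            raise IntegrationError(
                f"no sustaining amplitude below {hi} µM for T={period} h")
    if on_survives(lo):
        return lo
    while hi - lo > max(tol, 1e-3 * hi):
        mid = 0.5 * (lo + hi)
        if on_survives(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def matched_period_curve(periods: Sequence[float] = (1.0, 3.0, 5.0, 6.0),
                         params: BiofilmParams | None = None,
                         effects: GrowthEffects = GrowthEffects(),
                         tol: float = 1e-3) -> ThresholdCurve:
    """Thresholds where the oscillation period equals the cell-cycle length.

    For each period T the growth rate is ln2/T (one pulse per cycle) and
    the cosine deactivation threshold is computed at that growth rate.
    """
    if len(periods) < 4:
        raise ValueError("need at least 4 matched periods to fit the power law")
    taus, ms = [], []
    for T in periods:
        g = math.log(2) / T
        ms.append(oscillatory_threshold(T, g, params, effects, tol=tol))
        taus.append(T)
    return ThresholdCurve(np.array(taus), np.array(ms),
                          abscissa_name="tau_cyc_h", input_class="cosine")


def power_law_fit(curve: ThresholdCurve,
                  x0: tuple[float, float, float] = (0.05, 2.0, 0.1),
                  n_starts: int = 5, seed: int = 0) -> PowerLawFit:
    """Nonlinear least squares of MOFF = a*tau^b + c.

    Multi-start (jittered initial guesses) with positivity bounds on a and
    c guards against local minima; returns the best fit and its R².
    """
    tau, y = curve.abscissa, curve.thresholds
    if tau.size < 3:
        raise ValueError("need at least as many points as parameters")

    def resid(p):
        a, b, c = p
        return a * tau ** b + c - y

    rng = np.random.default_rng(seed)
    best = None
    for k in range(n_starts):
        start = np.array(x0, float)
        if k:
            start = start * rng.uniform(0.5, 2.0, 3)
        try:
            sol = least_squares(resid, start,
                                bounds=([0.0, -10.0, 0.0], [np.inf, 10.0, np.inf]))
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    a, b, c = best.x
    ss_res = float(np.sum(resid(best.x) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(float(a), float(b), float(c), r2)
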