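"""Deterministic model of the SinI/SinR/SlrR/TapA matrix-production network.

Spo0A~P induces *sinI*; the SinI dimer sequesters the SinR dimer in an IR
heterocomplex.  Free SinR dimers tetramerise, and the tetramer represses
*slrR* and *tapA*.  SlrR dimers also sequester SinR (LR complex), closing a
double-negative SinR/SlrR loop that makes the network bistable: a matrix-ON
state (SinR sequestered, TapA high) coexists with a matrix-OFF state (SinR
free, TapA repressed) over a range of Spo0A~P inputs.

Growth enters three ways:

* gene dosage — production scales with the average copy number
  n = 2^(1 - tau_rep*p/tau_cyc) of each gene (oriC-proximal *slrR* loses
  its dosage advantage over terminus-proximal *sinR* as growth slows);
* protein dilution — the effective degradation is kdegpro + g
  (optionally frozen at a reference g0);
* cell size — all production scales with F(g).

State vector (µM): [I_d, R, R_T, L, LR, IR, TapA] where I_d is the SinI
dimer (SinI is produced directly in dimer form), R the SinR dimer, R_T the
SinR tetramer, L the SlrR dimer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp

from .cellcycle import (CycleTiming, GenePosition, SizeFactorParams,
                        average_copy_number, size_factor, timing_from_growth)
from .phosphorelay import IntegrationError, PhosphorelayParams, periodic_pulse
from .signals import Signal

__all__ = [
    "BIOFILM_SPECIES",
    "BiofilmGene",
    "BiofilmParams",
    "GrowthEffects",
    "sinI_rate",
    "slrR_rate",
    "tapA_rate",
    "sinR_rate",
    "effective_degradation",
    "biofilm_rhs",
    "simulate_biofilm",
    "steady_state",
    "on_off_states",
    "branch_midpoint",
    "classify_state",
    "find_deactivation_cycle",
    "DeactivationResult",
]

BIOFILM_SPECIES = ("SinI_d", "SinR", "SinR_T", "SlrR", "LR", "IR", "TapA")
IDX_TAPA = BIOFILM_SPECIES.index("TapA")


@dataclass(frozen=True)
class BiofilmGene:
    """Transcription parameters of one matrix-network gene."""

    v0: float        # basal transcription rate, µM/h
    vmax: float      # regulated transcription rate, µM/h
    K: float         # half-maximal constant, µM ([0A~P] for sinI, [R_T] else)
    ktran: float     # translation rate, 1/h
    p: float         # fractional chromosomal position relative to oriC


@dataclass
class BiofilmParams:
    """Parameterisation of the matrix-production network (units µM, h)."""

    sinI: BiofilmGene
    sinR: BiofilmGene
    slrR: BiofilmGene
    tapA: BiofilmGene
    kdegm: float = 8.3          # mRNA degradation, 1/h
    kdegpro: float = 0.2        # protein degradation, 1/h
    kdegpro_slrR: float = 0.8   # SlrR is unstable
    kdegpro_sinI: float = 0.2   # free SinI turnover (unstable antagonist)
    kdegpro_lr: float = 0.2     # turnover of the SlrR·SinR (LR) complex
    kon_rt: float = 10.0        # SinR dimer tetramerisation, 1/(µM h)
    koff_rt: float = 10.0       # tetramer dissociation, 1/h
    kon_ir: float = 50.0        # SinI·SinR association, 1/(µM h)
    koff_ir: float = 1.0        # IR dissociation, 1/h
    kon_lr: float = 50.0        # SlrR·SinR association, 1/(µM h)
    koff_lr: float = 1.0        # LR dissociation, 1/h
    size: SizeFactorParams = field(default_factory=SizeFactorParams)

    @classmethod
    def from_dict(cls, d: dict) -> "BiofilmParams":
        genes = {k: BiofilmGene(**d[k]) for k in ("sinI", "sinR", "slrR", "tapA")}
        size = SizeFactorParams(**d.get("size", {}))
        kw = {k: v for k, v in d.items()
              if k not in ("sinI", "sinR", "slrR", "tapA", "size")}
        return cls(size=size, **genes, **kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BiofilmParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "BiofilmParams":
        ref = resources.files("spopulse").joinpath("params/biofilm.yaml")
        return cls.from_dict(yaml.safe_load(ref.read_text()))


@dataclass(frozen=True)
class GrowthEffects:
    """Which growth-rate effects act on the matrix network.

    ``dilution``: protein removal is kdegpro + g (True) or kdegpro + g0
    (False).  ``dosage``: average copy numbers follow the live cycle
    timing (True) or are frozen at the reference timing (False).
    ``g0``: reference growth rate for the frozen variants, 1/h.
    """

    dilution: bool = True
    dosage: bool = True
    g0: float = 0.2

    def reference_timing(self) -> CycleTiming:
        return timing_from_growth(self.g0)


def effective_degradation(kdegpro: float, g: float) -> float:
    """Effective protein removal rate kdegpro + g (degradation + dilution)."""
    if kdegpro < 0 or g < 0:
        raise ValueError("rates must be non-negative")
    return kdegpro + g


def _dosage(gene: BiofilmGene, timing: CycleTiming) -> float:
    return average_copy_number(GenePosition(gene.p), timing)


def sinI_rate(c0A: float, n: float, Fg: float, params: BiofilmParams) -> float:
    """SinI production: (vi0 + vimax*c/(Ki+c)) * n*Fg * ktran/kdegm, µM/h."""
    gn = params.sinI
    if gn.K <= 0:
        raise ValueError("Ki must be positive")
    c = max(c0A, 0.0)
    return (gn.v0 + gn.vmax * c / (gn.K + c)) * n * Fg * gn.ktran / params.kdegm


def _repressed_rate(gn: BiofilmGene, RT: float, n: float, Fg: float,
                    kdegm: float) -> float:
    if gn.K <= 0:
        raise ValueError("repression constant must be positive")
    r = max(RT, 0.0)
    return (gn.v0 + gn.vmax * gn.K / (gn.K + r)) * n * Fg * gn.ktran / kdegm


def slrR_rate(RT: float, n: float, Fg: float, params: BiofilmParams) -> float:
    """SlrR production, repressed by the SinR tetramer, µM/h."""
    return _repressed_rate(params.slrR, RT, n, Fg, params.kdegm)


def tapA_rate(RT: float, n: float, Fg: float, params: BiofilmParams) -> float:
    """TapA production, repressed by the SinR tetramer, µM/h."""
    return _repressed_rate(params.tapA, RT, n, Fg, params.kdegm)


def sinR_rate(n: float, Fg: float, params: BiofilmParams) -> float:
    """Constitutive SinR production, µM/h."""
    gn = params.sinR
    return gn.v0 * n * Fg * gn.ktran / params.kdegm


def biofilm_rhs(t: float, y: np.ndarray, c0A_fn: Callable[[float], float],
                params: BiofilmParams, timing: CycleTiming,
                effects: GrowthEffects = GrowthEffects()) -> np.ndarray:
    """Derivative of the matrix-network state at time t.

    ``c0A_fn`` is the [0A~P] input; ``timing`` carries the live growth
    rate/cycle structure; ``effects`` selects which growth effects act.
    """
    Id, R, RT, L, LR, IR, T = y
    g_live = timing.growth_rate
    Fg = size_factor(g_live, params.size)
    dos_timing = timing if effects.dosage else effects.reference_timing()
    g_dil = g_live if effects.dilution else effects.g0
    keff = effective_degradation(params.kdegpro, g_dil)
    # SlrR and SinI are unstable as free proteins; in the LR/IR complexes
    # they are protected and turn over at the common protein rate
    keff_L = effective_degradation(params.kdegpro_slrR, g_dil)
    keff_I = effective_degradation(params.kdegpro_sinI, g_dil)
    keff_LR = effective_degradation(params.kdegpro_lr, g_dil)

    c = c0A_fn(t)
    v_i = sinI_rate(c, _dosage(params.sinI, dos_timing), Fg, params)
    v_r = sinR_rate(_dosage(params.sinR, dos_timing), Fg, params)
    v_l = slrR_rate(RT, _dosage(params.slrR, dos_timing), Fg, params)
    v_t = tapA_rate(RT, _dosage(params.tapA, dos_timing), Fg, params)

    a_rt = params.kon_rt * R * R
    d_rt = params.koff_rt * RT
    a_ir = params.kon_ir * Id * R
    d_ir = params.koff_ir * IR
    a_lr = params.kon_lr * L * R
    d_lr = params.koff_lr * LR

    return np.array([
        v_i - a_ir + d_ir - keff_I * Id,                         # SinI dimer
        v_r - 2 * a_rt + 2 * d_rt - a_ir + d_ir - a_lr + d_lr - keff * R,
        a_rt - d_rt - keff * RT,                                 # SinR tetramer
        v_l - a_lr + d_lr - keff_L * L,                          # SlrR dimer
        a_lr - d_lr - keff_LR * LR,
        a_ir - d_ir - keff * IR,
        v_t - keff * T,                                          # TapA
    ])


def _as_input_fn(inp) -> Callable[[float], float]:
    if isinstance(inp, Signal):
        return inp.interpolator()
    if callable(inp):
        return inp
    level = float(inp)
    return lambda t: level


def simulate_biofilm(params: BiofilmParams, inp, timing: CycleTiming | float,
                     duration: float, y0: np.ndarray | None = None,
                     effects: GrowthEffects = GrowthEffects(),
                     dt_out: float = 0.01, rtol: float = 1e-7,
                     atol: float = 1e-10):
    """Integrate the matrix network under an [0A~P] input.

    ``inp`` may be a :class:`Signal`, a callable t -> µM, or a constant.
    Returns ``(times, states)`` with states of shape (7, n_times).
    """
    if isinstance(timing, (int, float)):
        timing = timing_from_growth(float(timing))
    y0 = np.zeros(len(BIOFILM_SPECIES)) if y0 is None else np.asarray(y0, float)
    if duration <= 0:
        return np.array([0.0]), y0[:, None].copy()
    c0A_fn = _as_input_fn(inp)
    fun = lambda t, y: biofilm_rhs(t, y, c0A_fn, params, timing, effects)
    t_eval = np.clip(np.arange(0.0, duration + dt_out / 2, dt_out),
                     0.0, duration)
    sol = solve_ivp(fun, (0.0, duration), y0, method="LSODA", t_eval=t_eval,
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(f"biofilm integration failed: {sol.message}")
    return sol.t, sol.y


def steady_state(params: BiofilmParams, c0A: float, timing: CycleTiming | float,
                 y0: np.ndarray | None = None,
                 effects: GrowthEffects = GrowthEffects(),
                 horizon: float = 300.0, tol: float = 1e-6) -> np.ndarray:
    """Steady state under a constant input, from an optional initial state.

    Integrates ``horizon`` hours and verifies max |dX/dt|/(|X|+eps) < tol,
    extending in 50 h blocks (up to 400 h total) if needed.
    """
    if isinstance(timing, (int, float)):
        timing = timing_from_growth(float(timing))
    y = np.zeros(len(BIOFILM_SPECIES)) if y0 is None else np.asarray(y0, float)
    eps = 1e-9
    t_total = 0.0
    block = horizon
    while True:
        _, ys = simulate_biofilm(params, c0A, timing, block, y, effects)
        y = ys[:, -1]
        t_total += block
        deriv = biofilm_rhs(0.0, y, lambda t: c0A, params, timing, effects)
        if np.max(np.abs(deriv) / (np.abs(y) + eps)) < tol:
            return y
        if t_total >= 400.0:
            raise IntegrationError(
                f"no steady state within {t_total:.0f} h at c0A={c0A}")
        block = 50.0


def on_off_states(params: BiofilmParams, c0A: float,
                  timing: CycleTiming | float,
                  effects: GrowthEffects = GrowthEffects()):
    """ON- and OFF-initialised steady states under a constant input.

    The OFF start is the empty state; the ON start is the steady state
    under a strongly saturating input.  Returns ``(state_on, state_off)``.
    """
    if isinstance(timing, (int, float)):
        timing = timing_from_growth(float(timing))
    off0 = steady_state(params, 0.0, timing, None, effects)
    on = steady_state(params, c0A, timing, _on_seed(), effects)
    off = steady_state(params, c0A, timing, off0, effects)
    return on, off


def _on_seed() -> np.ndarray:
    """A state deep in the matrix-ON basin (SinR fully sequestered)."""
    # order: SinI_d, SinR, SinR_T, SlrR, LR, IR, TapA
    return np.array([2.0, 0.0, 0.0, 5.0, 8.0, 2.0, 4.0])


_MIDPOINT_CACHE: dict[int, float] = {}


def branch_midpoint(params: BiofilmParams,
                    phos_params: PhosphorelayParams | None = None,
                    g_ref: float = 0.2) -> float:
    """ON/OFF classification midpoint for TapA (µM).

    Geometric mean of the two branch TapA values at the reference growth
    rate with a constant input equal to the natural-pulse mean; computed
    once per parameterisation and cached.
    """
    key = id(params)
    if key in _MIDPOINT_CACHE:
        return _MIDPOINT_CACHE[key]
    if phos_params is None:
        phos_params = PhosphorelayParams.default()
    timing = timing_from_growth(g_ref)
    c_ref = periodic_pulse(phos_params, timing).mean()
    on, off = on_off_states(params, c_ref, timing)
    mid = math.sqrt(max(on[IDX_TAPA], 1e-12) * max(off[IDX_TAPA], 1e-12))
    _MIDPOINT_CACHE[key] = mid
    return mid


def classify_state(tapA: float, midpoint: float) -> str:
    """'ON' if TapA exceeds the branch midpoint, else 'OFF'."""
    return "ON" if tapA > midpoint else "OFF"


@dataclass
class DeactivationResult:
    """Outcome of a deactivation-cycle search."""

    tau_cyc: float | None       # first cycle length classified OFF, h
    searched_up_to: float       # largest cycle length tested, h
    history: list               # (tau_cyc, mean TapA, 'ON'/'OFF') triples

    @property
    def found(self) -> bool:
        return self.tau_cyc is not None


def _candidate_timing(tau_cyc: float, mode: str, base: CycleTiming) -> CycleTiming:
    """Timing for a candidate cycle length under a growth scenario.

    ``mode`` 'natural': g = ln2/tau_cyc with tau_rep(g) from the replication
    law; 'replication': extra cycle time extends tau_rep only;
    'post': extra cycle time extends tau_post only.  In the phase-growth
    modes the dilution/size growth rate is ln2/tau_cyc of the modified cycle.
    """
    if mode == "natural":
        return timing_from_growth(math.log(2) / tau_cyc)
    g = math.log(2) / tau_cyc
    extra = tau_cyc - base.tau_cyc
    if extra < -1e-9:
        raise ValueError("candidate cycle shorter than the baseline")
    if mode == "replication":
        return CycleTiming(g, base.tau_rep + extra, tau_cyc)
    if mode == "post":
        return CycleTiming(g, base.tau_rep, tau_cyc)
    raise ValueError(f"unknown growth mode {mode!r}")


def _mean_tapA_under_pulse(params: BiofilmParams, phos: PhosphorelayParams,
                           timing: CycleTiming, y0: np.ndarray,
                           effects: GrowthEffects, pulsing: bool,
                           horizon: float = 120.0) -> float:
    """Cycle-averaged TapA after a long simulation under the cycle's input.

    The input is the natural pulse regenerated at the candidate timing
    (or its mean, for the constant-input scenario), extended periodically.
    Integration continues in 50 h blocks until the per-cycle mean TapA
    drifts by < 1e-3 (relative) or 400 h are reached.
    """
    pulse = periodic_pulse(phos, timing)
    period = timing.tau_cyc
    if pulsing:
        pulse_fn = pulse.interpolator()

        def make_fn(t_offset):
            return lambda t: pulse_fn((t + t_offset) % period)
    else:
        level = pulse.mean()

        def make_fn(t_offset):
            return lambda t: level

    y = y0.copy()
    t_done, prev_mean = 0.0, None
    block = horizon
    while True:
        ts, ys = simulate_biofilm(params, make_fn(t_done), timing, block, y,
                                  effects)
        y = ys[:, -1]
        t_done += block
        sel = ts >= ts[-1] - period
        mean_tap = float(np.trapezoid(ys[IDX_TAPA, sel], ts[sel]) /
                         (ts[sel][-1] - ts[sel][0]))
        if prev_mean is not None and \
                abs(mean_tap - prev_mean) < 1e-3 * (abs(mean_tap) + 1e-9):
            return mean_tap
        if t_done >= 400.0:
            return mean_tap
        prev_mean = mean_tap
        block = 50.0


def find_deactivation_cycle(params: BiofilmParams | None = None,
                            phos_params: PhosphorelayParams | None = None,
                            effects: GrowthEffects = GrowthEffects(),
                            pulsing: bool = True,
                            mode: str = "natural",
                            g_start: float = 0.2,
                            step: float = 0.1,
                            ceiling: float = 20.0,
                            midpoint: float | None = None) -> DeactivationResult:
    """Minimal cell-cycle length at which the matrix deactivates.

    Starting from the matrix-ON state at ``g_start``, cycle lengths are
    examined on a ``step``-spaced grid from the baseline upward; for each
    candidate the Spo0A~P input is regenerated at the candidate timing,
    the network is integrated to its (periodic) steady state and the end
    state is classified against the branch midpoint.  The end-state mean
    TapA is monotone in the cycle length for all scenarios handled here,
    so the first OFF grid point is located by bisection on the grid.

    Returns a :class:`DeactivationResult`; ``tau_cyc`` is None if no
    deactivation occurs below ``ceiling``.
    """
    params = params or BiofilmParams.default()
    phos_params = phos_params or PhosphorelayParams.default()
    if midpoint is None:
        midpoint = branch_midpoint(params, phos_params, g_ref=g_start)
    base = timing_from_growth(g_start)
    # matrix-ON initial state at the baseline growth rate
    c_ref = periodic_pulse(phos_params, base).mean()
    y_on = steady_state(params, c_ref, base, _on_seed())

    history = []

    def is_off(k: int) -> bool:
        tau = base.tau_cyc + k * step
        timing = _candidate_timing(tau, mode, base)
        mean_tap = _mean_tapA_under_pulse(params, phos_params, timing, y_on,
                                          effects, pulsing)
        state = classify_state(mean_tap, midpoint)
        history.append((tau, mean_tap, state))
        return state == "OFF"

    k_max = int(math.floor((ceiling - base.tau_cyc) / step))
    if is_off(0):
        return DeactivationResult(base.tau_cyc, base.tau_cyc, history)
    if not is_off(k_max):
        return DeactivationResult(None, base.tau_cyc + k_max * step, history)
    lo, hi = 0, k_max            # lo ON, hi OFF
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if is_off(mid):
            hi = mid
        else:
            lo = mid
    tau = base.tau_cyc + hi * step
    return DeactivationResult(tau, tau, history)
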