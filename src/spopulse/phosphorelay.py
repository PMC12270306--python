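"""Deterministic ODE model of the Spo0A phosphorelay.

The model couples six genes (*kinA*, *spo0F*, *spo0B*, *spo0A*, *rap*,
*spo0E*) to the KinA -> Spo0F~P -> Spo0B~P -> Spo0A~P phosphotransfer chain:

* transcription initiation is a Hill function of [Spo0A~P] scaled by the
  cell-size factor F(g) (:func:`spopulse.cellcycle.size_factor`);
* the realised production rate ``vpc`` relaxes toward the initiation rate
  ``vpi`` with first-order constant ``kdel`` (transcription/translation
  delay) and is multiplied by the gene's current copy number;
* KinA autophosphorylates, inhibited by unphosphorylated Spo0F in
  proportion to the Spo0F:KinA ratio (sequestration-like); the
  phosphoryl group is relayed F -> B -> A by mass-action transfer; Rap
  and Spo0E dephosphorylate Spo0F~P and Spo0A~P;
* every protein is removed at ``kdeg + g`` (degradation plus dilution).

The once-per-cycle Spo0A~P pulse emerges from the chromosomal arrangement
of *kinA* (terminus-proximal, p = 1) and *spo0F* (*oriC*-proximal, p = 0):
during DNA replication the dosage ratio kinA:spo0F is 1:2, surplus Spo0F
inhibits KinA and [0A~P] stays low; once *kinA* is replicated the balance
is restored and [0A~P] overshoots until division.

Rate constants live in ``params/phosphorelay.yaml`` and are this package's
own calibration (see docs/methods.md); nothing is hard-coded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp

from .cellcycle import (CycleTiming, GenePosition, SizeFactorParams,
                        size_factor, timing_from_growth)
from .signals import Signal

__all__ = [
    "GENES",
    "GeneParams",
    "PhosphorelayParams",
    "hill_production",
    "delay_update",
    "dosage_scaled_rate",
    "phosphorelay_rhs",
    "simulate_phosphorelay",
    "simulate_phosphorelay_varying",
    "periodic_pulse",
    "tile_cycles",
    "IntegrationError",
]

#: gene order; each gene produces the unphosphorylated form of its protein
GENES = ("kinA", "spo0F", "spo0B", "spo0A", "rap", "spo0E")

#: state layout: proteins then delayed production rates
SPECIES = ("KinA", "KinA_P", "Spo0F", "Spo0F_P", "Spo0B", "Spo0B_P",
           "Spo0A", "Spo0A_P", "Rap", "Spo0E")
N_PROT = len(SPECIES)
IDX_AP = SPECIES.index("Spo0A_P")
#: index of the unphosphorylated protein produced by each gene
_PROD_IDX = (0, 2, 4, 6, 8, 9)


class IntegrationError(RuntimeError):
    """ODE solver failure, with solver diagnostics in the message."""


@dataclass(frozen=True)
class GeneParams:
    """Transcription parameters and chromosomal position for one gene."""

    vb: float          # basal initiation rate, µM/h (per unit F(g), per copy)
    vmax: float        # maximal 0A~P-induced rate, µM/h
    K: float           # half-maximal [0A~P], µM
    m: float           # Hill exponent (>= 1)
    p: float           # fractional chromosomal position, 0 = oriC

    def __post_init__(self) -> None:
        if min(self.vb, self.vmax) < 0 or self.K <= 0 or self.m < 1:
            raise ValueError(f"invalid gene parameters {self}")


@dataclass
class PhosphorelayParams:
    """Full parameterisation of the phosphorelay model (units µM, h)."""

    genes: dict[str, GeneParams]
    kdel: float                 # delay relaxation constant, 1/h
    ka: float                   # KinA autophosphorylation, 1/h
    K_inh: float                # Spo0F:KinA ratio at half-maximal inhibition
    inh_exp: float              # Hill exponent of the Spo0F inhibition
    kp_kf: float                # KinA~P + Spo0F transfer, 1/(µM h)
    kp_fb: float                # Spo0F~P + Spo0B transfer, 1/(µM h)
    kp_ba: float                # Spo0B~P + Spo0A transfer, 1/(µM h)
    kph_f: float                # Rap dephosphorylation of Spo0F~P, 1/(µM h)
    kph_a: float                # Spo0E dephosphorylation of Spo0A~P, 1/(µM h)
    kdeg: float                 # intrinsic relay-protein degradation, 1/h
    kdeg_kin: float = 0.0       # extra intrinsic degradation of KinA forms, 1/h
    kdeg_f: float = 0.0         # extra intrinsic degradation of Spo0F forms, 1/h
    kdeg_ph: float = 0.0        # extra intrinsic degradation of Rap/Spo0E, 1/h
    size: SizeFactorParams = field(default_factory=SizeFactorParams)

    def __post_init__(self) -> None:
        missing = set(GENES) - set(self.genes)
        if missing:
            raise ValueError(f"missing gene parameters for {sorted(missing)}")
        for name in ("kdel", "ka", "K_inh", "kp_kf", "kp_fb", "kp_ba",
                     "kph_f", "kph_a", "kdeg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_dict(cls, d: dict) -> "PhosphorelayParams":
        genes = {k: GeneParams(**v) for k, v in d["genes"].items()}
        size = SizeFactorParams(**d.get("size", {}))
        kw = {k: v for k, v in d.items() if k not in ("genes", "size")}
        return cls(genes=genes, size=size, **kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhosphorelayParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "PhosphorelayParams":
        ref = resources.files("spopulse").joinpath("params/phosphorelay.yaml")
        return cls.from_dict(yaml.safe_load(ref.read_text()))

    def positions(self) -> dict[str, GenePosition]:
        return {name: GenePosition(gp.p) for name, gp in self.genes.items()}


def hill_production(vb: float, vmax: float, K: float, m: float,
                    x: float, Fg: float) -> float:
    """Hill-activated initiation rate (vb + vmax*x^m/(K^m + x^m)) * Fg.

    Bounded in [vb*Fg, (vb+vmax)*Fg]; ``x`` is the activator ([0A~P]) level.
    """
    if K <= 0:
        raise ValueError("half-maximal constant K must be positive")
    if min(vb, vmax, m, x, Fg) < 0:
        raise ValueError("hill_production arguments must be non-negative")
    xm = x ** m
    return (vb + vmax * xm / (K ** m + xm)) * Fg


def delay_update(vpi: float, vpc: float, kdel: float) -> float:
    """d(vpc)/dt = kdel*(vpi - vpc): first-order relaxation toward vpi."""
    return kdel * (vpi - vpc)


def dosage_scaled_rate(vpc: float, n: float) -> float:
    """Production rate scaled by gene copy number, v = n * vpc."""
    return n * vpc


def phosphorelay_rhs(t: float, y: np.ndarray, params: PhosphorelayParams,
                     copy_numbers: Sequence[float], g: float) -> np.ndarray:
    """Time derivative of the phosphorelay state.

    ``copy_numbers`` are the current per-gene copy numbers (constant within
    an integration segment); ``g`` is the growth rate used for dilution and
    the size factor.
    """
    K, Kp, F, Fp, B, Bp, A, Ap, R, E = y[:N_PROT]
    vpc = y[N_PROT:]
    Fg = size_factor(g, params.size)
    kout = params.kdeg + g
    kout_kin = params.kdeg + params.kdeg_kin + g
    kout_f = params.kdeg + params.kdeg_f + g
    kout_ph = params.kdeg + params.kdeg_ph + g

    # production (delay-filtered, dosage-scaled)
    prod = np.zeros(N_PROT)
    dvpc = np.empty(len(GENES))
    for i, name in enumerate(GENES):
        gp = params.genes[name]
        vpi = hill_production(gp.vb, gp.vmax, gp.K, gp.m, max(Ap, 0.0), Fg)
        dvpc[i] = delay_update(vpi, vpc[i], params.kdel)
        prod[_PROD_IDX[i]] += dosage_scaled_rate(vpc[i], copy_numbers[i])

    # phosphotransfer chain; KinA autophosphorylation is inhibited by free
    # (unphosphorylated) Spo0F in proportion to the Spo0F:KinA ratio, the
    # sequestration-like readout of the kinA:spo0F dosage balance
    ktot = max(K + Kp, 1e-12)
    ratio = max(F, 0.0) / (params.K_inh * ktot)
    inhib = 1.0 / (1.0 + ratio ** params.inh_exp)
    phi_auto = params.ka * K * inhib
    phi_kf = params.kp_kf * Kp * F
    phi_fb = params.kp_fb * Fp * B
    phi_ba = params.kp_ba * Bp * A
    deph_f = params.kph_f * R * Fp
    deph_a = params.kph_a * E * Ap

    dy = np.empty_like(y)
    dy[0] = prod[0] - phi_auto + phi_kf - kout_kin * K      # KinA
    dy[1] = phi_auto - phi_kf - kout_kin * Kp               # KinA~P
    dy[2] = prod[2] - phi_kf + phi_fb + deph_f - kout_f * F  # Spo0F
    dy[3] = phi_kf - phi_fb - deph_f - kout_f * Fp           # Spo0F~P
    dy[4] = prod[4] - phi_fb + phi_ba - kout * B            # Spo0B
    dy[5] = phi_fb - phi_ba - kout * Bp                     # Spo0B~P
    dy[6] = prod[6] - phi_ba + deph_a - kout * A            # Spo0A
    dy[7] = phi_ba - deph_a - kout * Ap                     # Spo0A~P
    dy[8] = prod[8] - kout_ph * R                           # Rap
    dy[9] = prod[9] - kout_ph * E                           # Spo0E
    dy[N_PROT:] = dvpc
    return dy


def _cycle_segments(params: PhosphorelayParams, timing: CycleTiming):
    """Breakpoints and per-segment copy numbers for one cell cycle.

    Returns (edges, copies) where ``edges`` are the segment boundaries in
    [0, tau_cyc] and ``copies[j]`` is the per-gene copy-number vector on
    segment j.  Genes double at p * tau_rep; copy numbers reset to 1 at
    division, except p = 0 genes which sit at 2 throughout.
    """
    offsets = {name: params.genes[name].p * min(timing.tau_rep, timing.tau_cyc)
               for name in GENES}
    edges = sorted({0.0, timing.tau_cyc}
                   | {v for v in offsets.values() if 0.0 < v < timing.tau_cyc})
    copies = []
    for lo in edges[:-1]:
        copies.append([2.0 if lo >= offsets[name] else 1.0 for name in GENES])
    return np.asarray(edges), np.asarray(copies)


def _integrate_segment(fun, t0, t1, y0, t_eval, rtol, atol):
    sol = solve_ivp(fun, (t0, t1), y0, method="LSODA", t_eval=t_eval,
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(
            f"phosphorelay integration failed on [{t0:.3f}, {t1:.3f}] h: "
            f"{sol.message}")
    return sol


def simulate_phosphorelay(params: PhosphorelayParams,
                          timing: CycleTiming | float,
                          n_cycles: int = 8,
                          dt: float = 0.005,
                          discard_cycles: int = 3,
                          y0: np.ndarray | None = None,
                          rtol: float = 1e-8,
                          atol: float = 1e-10,
                          return_full: bool = False):
    """Simulate the phosphorelay for ``n_cycles`` cell cycles at fixed timing.

    Integration is segmented at every gene-replication event and at every
    division; the state is carried across segments (dilution is continuous,
    concentrations are not halved at division — only copy numbers reset).

    Parameters
    ----------
    timing : CycleTiming or float
        Cycle timing, or a growth rate from which the natural timing is
        derived.  Use :meth:`CycleTiming.with_overrides` for scenarios in
        which tau_rep or tau_post is varied independently.
    discard_cycles : int
        Number of initial cycles dropped from the returned trace
        (transient removal).

    Returns
    -------
    Signal
        [Spo0A~P] on a uniform grid (µM).  With ``return_full=True``,
        returns ``(signal, times, states)`` with the full state history.
    """
    if isinstance(timing, (int, float)):
        timing = timing_from_growth(float(timing))
    if discard_cycles >= n_cycles:
        raise ValueError("discard_cycles must be < n_cycles")
    edges, copies = _cycle_segments(params, timing)
    g = timing.growth_rate
    y = np.zeros(N_PROT + len(GENES)) if y0 is None else np.array(y0, dtype=float)

    all_t: list[np.ndarray] = []
    all_y: list[np.ndarray] = []
    for cyc in range(n_cycles):
        t_base = cyc * timing.tau_cyc
        for j in range(len(edges) - 1):
            t0, t1 = t_base + edges[j], t_base + edges[j + 1]
            nums = copies[j]
            fun = lambda t, yy: phosphorelay_rhs(t, yy, params, nums, g)
            k0 = math.ceil((t0 - 1e-12) / dt)
            t_eval = np.arange(k0, math.floor((t1 + 1e-12) / dt) + 1) * dt
            t_eval = np.clip(t_eval[(t_eval >= t0 - 1e-12)
                                     & (t_eval <= t1 + 1e-12)], t0, t1)
            te = t_eval if (t_eval.size and t1 - t_eval[-1] < 1e-12) \
                else np.append(t_eval, t1)
            sol = _integrate_segment(fun, t0, t1, y, te, rtol, atol)
            y = sol.y[:, -1]
            if t_eval.size:
                all_t.append(sol.t[:t_eval.size])
                all_y.append(sol.y[:, :t_eval.size])
        # division: copy numbers reset implicitly at the next cycle's segments
    t = np.concatenate(all_t)
    ys = np.concatenate(all_y, axis=1)
    # drop duplicated segment-boundary points
    keep = np.concatenate(([True], np.diff(t) > dt / 2))
    t, ys = t[keep], ys[:, keep]
    t_cut = discard_cycles * timing.tau_cyc
    sel = t >= t_cut - 1e-9
    sig = Signal(t[sel] - t[sel][0], np.maximum(ys[IDX_AP, sel], 0.0))
    if return_full:
        return sig, t[sel] - t[sel][0], ys[:, sel]
    return sig


def simulate_phosphorelay_varying(params: PhosphorelayParams,
                                  g_of_t: Callable[[float], float],
                                  t_end: float,
                                  dt: float = 0.005,
                                  y0: np.ndarray | None = None,
                                  rtol: float = 1e-8,
                                  atol: float = 1e-10):
    """Simulate under a time-varying growth schedule ``g_of_t``.

    A cycle ends when the accumulated growth satisfies the division
    criterion ``integral of g dt = ln 2`` over the cycle.  The replication
    period of each cycle is evaluated from g at cycle start and held fixed
    within the cycle; dilution and the size factor follow g(t) live.

    Returns ``(signal, cycle_boundaries)`` where ``signal`` is the [0A~P]
    trace from t = 0 (no transient removal) and ``cycle_boundaries`` the
    division times.
    """
    from scipy.integrate import quad

    y = np.zeros(N_PROT + len(GENES)) if y0 is None else np.array(y0, dtype=float)
    all_t, all_ap = [], []
    boundaries = [0.0]
    t_now = 0.0
    while t_now < t_end - 1e-9:
        g_start = g_of_t(t_now)
        tau_rep = 0.78 + 0.15 / g_start
        # find division time: integral of g from t_now reaches ln 2
        target = math.log(2)
        acc, t_div, step = 0.0, t_now, dt
        while acc < target and t_div < t_end + 10.0:
            acc += g_of_t(t_div + step / 2) * step
            t_div += step
        tau_cyc = t_div - t_now
        offsets = {name: params.genes[name].p * min(tau_rep, tau_cyc)
                   for name in GENES}
        edges = sorted({0.0, tau_cyc}
                       | {v for v in offsets.values() if 0.0 < v < tau_cyc})
        for j in range(len(edges) - 1):
            t0, t1 = t_now + edges[j], t_now + edges[j + 1]
            nums = [2.0 if edges[j] >= offsets[name] else 1.0 for name in GENES]
            fun = lambda t, yy: phosphorelay_rhs(t, yy, params, nums, g_of_t(t))
            k0 = math.ceil((t0 - 1e-12) / dt)
            t_eval = np.arange(k0, math.floor((t1 + 1e-12) / dt) + 1) * dt
            t_eval = np.clip(t_eval[(t_eval >= t0 - 1e-12)
                                     & (t_eval <= t1 + 1e-12)], t0, t1)
            te = t_eval if (t_eval.size and t1 - t_eval[-1] < 1e-12) \
                else np.append(t_eval, t1)
            sol = _integrate_segment(fun, t0, t1, y, te, rtol, atol)
            y = sol.y[:, -1]
            if t_eval.size:
                all_t.append(sol.t[:t_eval.size])
                all_ap.append(np.maximum(sol.y[IDX_AP, :t_eval.size], 0.0))
        t_now = t_div
        boundaries.append(t_now)
    t = np.concatenate(all_t)
    ap = np.concatenate(all_ap)
    keep = np.concatenate(([True], np.diff(t) > dt / 2))
    return Signal(t[keep], ap[keep]), np.asarray(boundaries)


def periodic_pulse(params: PhosphorelayParams, timing: CycleTiming | float,
                   dt: float = 0.005, settle_cycles: int = 12) -> Signal:
    """One post-transient cycle of the natural pulse, aligned to cycle start.

    Simulates ``settle_cycles`` cycles and returns the last full cycle on
    the grid [0, tau_cyc); tile with :func:`tile_cycles` to build long
    periodic inputs without re-integrating.
    """
    if isinstance(timing, (int, float)):
        timing = timing_from_growth(float(timing))
    sig = simulate_phosphorelay(params, timing, n_cycles=settle_cycles, dt=dt,
                                discard_cycles=settle_cycles - 1)
    n = int(round(timing.tau_cyc / dt))
    return Signal(sig.times[:n], sig.values[:n])


def tile_cycles(cycle_sig: Signal, n_cycles: int) -> Signal:
    """Tile a single-cycle signal periodically over ``n_cycles`` cycles."""
    dt = cycle_sig.dt
    n = cycle_sig.times.size
    values = np.concatenate([np.tile(cycle_sig.values, n_cycles),
                             [cycle_sig.values[0]]])
    times = np.arange(values.size) * dt
    return Signal(times, values, cycle_sig.units)
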