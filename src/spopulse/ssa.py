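"""Stochastic (Gillespie) model of the matrix-production network.

The deterministic network of :mod:`spopulse.biofilm_ode` is recast as a
chemical master equation with integer molecule counts and explicit
promoter dynamics:

* the *sinI* promoter switches OFF<->ON by Spo0A~P binding/unbinding (the
  input signal enters only through the binding propensity);
* the *slrR* and *tapA* promoters switch free<->repressed by SinR-tetramer
  binding/unbinding;
* transcription and translation are separate reactions per gene, so
  bursts propagate to the protein level;
* complex formation/dissociation and degradation mirror the ODE model.

Counts convert to concentrations via ``omega`` (molecules per µM); with
the default calibration the deterministic matrix-ON branch maps onto the
high mode of the TapA count distribution (~500 molecules) and the OFF
mode sits far below the 200-molecule classification threshold.

Exactness: within each refresh interval of the (piecewise-constant) input
the algorithm is the exact direct-method SSA; interval boundaries only
truncate the exponential waiting time, which is valid by memorylessness.

An optional promoter-locking extension (three extra reactions) lets the
*sinI* promoter enter a state in which the activator cannot bind and
transcription cannot occur, emulating additional transcriptional noise
sources such as supercoiling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from numba import njit

from .biofilm_ode import BiofilmParams, GrowthEffects
from .cellcycle import (CycleTiming, GenePosition, average_copy_number,
                        size_factor, timing_from_growth)
from .signals import Signal

__all__ = [
    "SSA_SPECIES",
    "IDX_TAP",
    "SSAParams",
    "SSAModel",
    "EnsembleResult",
    "build_matrix_ssa",
    "gillespie_simulate",
    "burn_in",
    "run_ensemble",
    "stochastic_cycle_ensemble",
]

SSA_SPECIES = (
    "PI_off", "PI_on", "PI_lock",
    "PL_free", "PL_rep", "PT_free", "PT_rep",
    "mRNA_sinI", "mRNA_sinR", "mRNA_slrR", "mRNA_tapA",
    "SinI_d", "SinR", "SinR_T", "SlrR", "LR", "IR", "TapA",
)
IDX_TAP = SSA_SPECIES.index("TapA")
_IDX = {name: i for i, name in enumerate(SSA_SPECIES)}

# propensity forms
_K0, _K1, _K2, _KDIMER, _KSIG = 0, 1, 2, 3, 4


@dataclass
class SSAParams:
    """Stochastic-model extras on top of :class:`BiofilmParams`.

    ``omega`` converts µM to molecules; ``ku_*`` are promoter unbinding
    rates (the binding rates follow from the deterministic half-maximal
    constants); the ``lock``/``unlock`` rates enable the promoter-locking
    extension when positive.
    """

    omega: float = 250.0        # molecules per µM
    ku_sinI: float = 10.0       # 1/h, 0A~P unbinding from the sinI promoter
    ku_slrR: float = 10.0       # 1/h, tetramer unbinding from slrR promoter
    ku_tapA: float = 10.0       # 1/h, tetramer unbinding from tapA promoter
    k_lock: float = 0.0         # 1/h, promoter locking (0 disables)
    k_unlock: float = 0.0       # 1/h, promoter unlocking
    refresh_dt: float = 0.005   # h, input refresh interval

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SSAParams":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "SSAParams":
        ref = resources.files("spopulse").joinpath("params/biofilm_ssa.yaml")
        return cls(**yaml.safe_load(ref.read_text()))


@dataclass
class SSAModel:
    """Reaction system with integer-count state.

    Arrays encode one reaction per row: ``rates`` (propensity constants),
    ``rtype`` (0 constant, 1 unimolecular, 2 bimolecular, 3 homodimer
    x(x-1)/2, 4 signal-modulated unimolecular), the participating species
    ``sp1``/``sp2`` and the dense stoichiometry matrix.
    """

    rates: np.ndarray
    rtype: np.ndarray
    sp1: np.ndarray
    sp2: np.ndarray
    stoich: np.ndarray
    omega: float
    refresh_dt: float
    locked: bool

    def n_reactions(self) -> int:
        return len(self.rates)

    def check_promoter_conservation(self, state: np.ndarray) -> bool:
        """Each promoter's states must sum to its copy number (1)."""
        i = _IDX
        return (state[i["PI_off"]] + state[i["PI_on"]] + state[i["PI_lock"]] == 1
                and state[i["PL_free"]] + state[i["PL_rep"]] == 1
                and state[i["PT_free"]] + state[i["PT_rep"]] == 1)


def _reaction(rows, rates, rtypes, sp1s, sp2s, n_sp, rate, rtype,
              sp1=-1, sp2=-1, changes=()):
    row = np.zeros(n_sp, dtype=np.int64)
    for idx, delta in changes:
        row[idx] += delta
    rows.append(row)
    rates.append(rate)
    rtypes.append(rtype)
    sp1s.append(sp1)
    sp2s.append(sp2)


def build_matrix_ssa(params: BiofilmParams | None = None,
                     ssa: SSAParams | None = None,
                     timing: CycleTiming | float = 0.4,
                     effects: GrowthEffects = GrowthEffects(),
                     locked: bool = False,
                     omega_scale: float = 1.0) -> SSAModel:
    """Build the stochastic matrix network for a fixed cycle timing.

    Rate constants are derived from the deterministic parameterisation so
    that the macroscopic limit of this model is exactly the ODE system
    (gene dosage enters as a propensity scale, the promoter copy number
    being 1 per gene).  ``omega_scale`` multiplies the µM-to-molecule
    conversion (system-size scaling; bimolecular propensities scale down
    accordingly).
    """
    params = params or BiofilmParams.default()
    ssa = ssa or SSAParams.default()
    if isinstance(timing, (int, float)):
        timing = timing_from_growth(float(timing), allow_overlap=True)
    om = ssa.omega * omega_scale
    g_live = timing.growth_rate
    Fg = size_factor(g_live, params.size)
    dos_t = timing if effects.dosage else effects.reference_timing()
    g_dil = g_live if effects.dilution else effects.g0
    keff = params.kdegpro + g_dil
    keff_L = params.kdegpro_slrR + g_dil
    keff_I = params.kdegpro_sinI + g_dil
    keff_LR = params.kdegpro_lr + g_dil

    def dos(gene):
        return average_copy_number(GenePosition(gene.p), dos_t)

    i = _IDX
    n_sp = len(SSA_SPECIES)
    rows, rates, rtypes, sp1s, sp2s = [], [], [], [], []
    add = lambda *a, **kw: _reaction(rows, rates, rtypes, sp1s, sp2s, n_sp,
                                     *a, **kw)

    # promoter switching (R1-R3): 0A~P binding at sinI, tetramer at slrR/tapA
    kb_i = ssa.ku_sinI / params.sinI.K            # 1/(µM h)
    add(kb_i, _KSIG, i["PI_off"],
        changes=[(i["PI_off"], -1), (i["PI_on"], +1)])
    add(ssa.ku_sinI, _K1, i["PI_on"],
        changes=[(i["PI_on"], -1), (i["PI_off"], +1)])
    kb_l = ssa.ku_slrR / (params.slrR.K * om)     # per RT molecule
    add(kb_l, _K2, i["PL_free"], i["SinR_T"],
        changes=[(i["PL_free"], -1), (i["SinR_T"], -1), (i["PL_rep"], +1)])
    add(ssa.ku_slrR, _K1, i["PL_rep"],
        changes=[(i["PL_rep"], -1), (i["PL_free"], +1), (i["SinR_T"], +1)])
    kb_t = ssa.ku_tapA / (params.tapA.K * om)
    add(kb_t, _K2, i["PT_free"], i["SinR_T"],
        changes=[(i["PT_free"], -1), (i["SinR_T"], -1), (i["PT_rep"], +1)])
    add(ssa.ku_tapA, _K1, i["PT_rep"],
        changes=[(i["PT_rep"], -1), (i["PT_free"], +1), (i["SinR_T"], +1)])

    # transcription (R4-R7), molecules/h; dosage and size factor fold in
    sI, sR, sL, sT = params.sinI, params.sinR, params.slrR, params.tapA
    add((sI.v0 + sI.vmax) * dos(sI) * Fg * om, _K1, i["PI_on"],
        changes=[(i["mRNA_sinI"], +1)])
    add(sI.v0 * dos(sI) * Fg * om, _K1, i["PI_off"],
        changes=[(i["mRNA_sinI"], +1)])
    add(sR.v0 * dos(sR) * Fg * om, _K0,
        changes=[(i["mRNA_sinR"], +1)])
    add((sL.v0 + sL.vmax) * dos(sL) * Fg * om, _K1, i["PL_free"],
        changes=[(i["mRNA_slrR"], +1)])
    add(sL.v0 * dos(sL) * Fg * om, _K1, i["PL_rep"],
        changes=[(i["mRNA_slrR"], +1)])
    add((sT.v0 + sT.vmax) * dos(sT) * Fg * om, _K1, i["PT_free"],
        changes=[(i["mRNA_tapA"], +1)])
    add(sT.v0 * dos(sT) * Fg * om, _K1, i["PT_rep"],
        changes=[(i["mRNA_tapA"], +1)])

    # mRNA degradation
    for m in ("mRNA_sinI", "mRNA_sinR", "mRNA_slrR", "mRNA_tapA"):
        add(params.kdegm, _K1, i[m], changes=[(i[m], -1)])

    # translation (R8-R11)
    add(sI.ktran, _K1, i["mRNA_sinI"], changes=[(i["SinI_d"], +1)])
    add(sR.ktran, _K1, i["mRNA_sinR"], changes=[(i["SinR"], +1)])
    add(sL.ktran, _K1, i["mRNA_slrR"], changes=[(i["SlrR"], +1)])
    add(sT.ktran, _K1, i["mRNA_tapA"], changes=[(i["TapA"], +1)])

    # complex formation / dissociation
    add(2.0 * params.kon_rt / om, _KDIMER, i["SinR"],
        changes=[(i["SinR"], -2), (i["SinR_T"], +1)])
    add(params.koff_rt, _K1, i["SinR_T"],
        changes=[(i["SinR_T"], -1), (i["SinR"], +2)])
    add(params.kon_ir / om, _K2, i["SinI_d"], i["SinR"],
        changes=[(i["SinI_d"], -1), (i["SinR"], -1), (i["IR"], +1)])
    add(params.koff_ir, _K1, i["IR"],
        changes=[(i["IR"], -1), (i["SinI_d"], +1), (i["SinR"], +1)])
    add(params.kon_lr / om, _K2, i["SlrR"], i["SinR"],
        changes=[(i["SlrR"], -1), (i["SinR"], -1), (i["LR"], +1)])
    add(params.koff_lr, _K1, i["LR"],
        changes=[(i["LR"], -1), (i["SlrR"], +1), (i["SinR"], +1)])

    # protein degradation (dilution included)
    for name, k in (("SinI_d", keff_I), ("SinR", keff), ("SinR_T", keff),
                    ("SlrR", keff_L), ("LR", keff_LR), ("IR", keff),
                    ("TapA", keff)):
        add(k, _K1, i[name], changes=[(i[name], -1)])

    if locked:
        if ssa.k_lock <= 0 or ssa.k_unlock <= 0:
            raise ValueError("locking requires positive k_lock and k_unlock")
        add(ssa.k_lock, _K1, i["PI_off"],
            changes=[(i["PI_off"], -1), (i["PI_lock"], +1)])
        add(ssa.k_lock, _K1, i["PI_on"],
            changes=[(i["PI_on"], -1), (i["PI_lock"], +1)])
        add(ssa.k_unlock, _K1, i["PI_lock"],
            changes=[(i["PI_lock"], -1), (i["PI_off"], +1)])

    return SSAModel(
        rates=np.asarray(rates, float),
        rtype=np.asarray(rtypes, np.int64),
        sp1=np.asarray(sp1s, np.int64),
        sp2=np.asarray(sp2s, np.int64),
        stoich=np.asarray(rows, np.int64),
        omega=om, refresh_dt=ssa.refresh_dt, locked=locked,
    )


def initial_state() -> np.ndarray:
    """All promoters free, no molecules."""
    s = np.zeros(len(SSA_SPECIES), dtype=np.int64)
    s[_IDX["PI_off"]] = 1
    s[_IDX["PL_free"]] = 1
    s[_IDX["PT_free"]] = 1
    return s


@njit(cache=True)
def _ssa_run(state, rates, rtype, sp1, sp2, stoich, c_vals, c_dt,
             t_end, rec_dt, rec_out, seed):
    """Direct-method SSA with piecewise-constant signal refresh.

    ``c_vals`` holds the signal (µM) on the refresh grid; ``rec_out`` is
    filled with the TapA count on the recording grid.  Returns the final
    state.
    """
    np.random.seed(seed)
    n_rxn = rates.shape[0]
    props = np.zeros(n_rxn)
    t = 0.0
    k_int = 0
    n_int = c_vals.shape[0]
    rec_i = 0
    n_rec = rec_out.shape[0]
    tap = IDX_TAP
    while True:
        c_now = c_vals[min(k_int, n_int - 1)]
        boundary = (k_int + 1) * c_dt
        if boundary > t_end:
            boundary = t_end
        # propensities are constant until the next boundary
        a_tot = 0.0
        for r in range(n_rxn):
            ty = rtype[r]
            if ty == 0:
                a = rates[r]
            elif ty == 1:
                a = rates[r] * state[sp1[r]]
            elif ty == 2:
                a = rates[r] * state[sp1[r]] * state[sp2[r]]
            elif ty == 3:
                x = state[sp1[r]]
                a = rates[r] * x * (x - 1) * 0.5
            else:
                a = rates[r] * c_now * state[sp1[r]]
            if a < 0.0:
                a = 0.0
            props[r] = a
            a_tot += a
        if a_tot <= 0.0:
            t_next = boundary
        else:
            t_next = t + (-math.log(np.random.random())) / a_tot
        if t_next >= boundary:
            # no event before the boundary: advance and re-draw (memoryless)
            t = boundary
            while rec_i < n_rec and rec_i * rec_dt <= t + 1e-12:
                rec_out[rec_i] = state[tap]
                rec_i += 1
            if boundary >= t_end:
                break
            k_int += 1
            continue
        # record grid points passed before the event
        while rec_i < n_rec and rec_i * rec_dt < t_next:
            rec_out[rec_i] = state[tap]
            rec_i += 1
        t = t_next
        u = np.random.random() * a_tot
        acc = 0.0
        chosen = n_rxn - 1
        for r in range(n_rxn):
            acc += props[r]
            if u < acc:
                chosen = r
                break
        for s in range(state.shape[0]):
            state[s] += stoich[chosen, s]
    while rec_i < n_rec:
        rec_out[rec_i] = state[tap]
        rec_i += 1
    return state


def _signal_on_grid(inp, duration: float, c_dt: float) -> np.ndarray:
    if isinstance(inp, Signal):
        f = inp.interpolator()
        n = int(math.ceil(duration / c_dt))
        return np.array([f((k + 0.5) * c_dt) for k in range(n)])
    if callable(inp):
        n = int(math.ceil(duration / c_dt))
        return np.array([float(inp((k + 0.5) * c_dt)) for k in range(n)])
    return np.full(max(int(math.ceil(duration / c_dt)), 1), float(inp))


def gillespie_simulate(model: SSAModel, inp, duration: float, seed: int,
                       y0: np.ndarray | None = None,
                       record_dt: float = 0.1):
    """Simulate one cell; returns ``(times, tapA_counts, final_state)``.

    ``inp`` is the Spo0A~P input in µM (Signal, callable or constant);
    it enters the sinI-promoter binding propensity, refreshed on the
    model's ``refresh_dt`` grid.  ``seed`` is mandatory: runs are exactly
    reproducible.
    """
    state = initial_state() if y0 is None else np.array(y0, dtype=np.int64)
    if np.any(state < 0):
        raise ValueError("negative initial counts")
    c_vals = _signal_on_grid(inp, duration, model.refresh_dt)
    n_rec = int(math.floor(duration / record_dt)) + 1
    rec = np.zeros(n_rec, dtype=np.int64)
    final = _ssa_run(state, model.rates, model.rtype, model.sp1, model.sp2,
                     model.stoich, c_vals, model.refresh_dt, duration,
                     record_dt, rec, seed & 0x7FFFFFFF)
    times = np.arange(n_rec) * record_dt
    return times, rec, final


def burn_in(model: SSAModel, inp, seed: int, duration: float = 60.0
            ) -> np.ndarray:
    """Final state of a preliminary stochastic simulation.

    The caller selects the burn-in input to match the desired initial
    macro-state: a zero (or sub-threshold) input yields a matrix-OFF
    state, a saturating input a matrix-ON state.
    """
    _, _, final = gillespie_simulate(model, inp, duration, seed)
    return final


@dataclass
class EnsembleResult:
    """Per-cell TapA trajectories on a shared grid, with bookkeeping."""

    times: np.ndarray            # h
    tapA: np.ndarray             # (n_cells, n_times) integer counts
    seed_base: int
    initially_on: bool

    @property
    def n_cells(self) -> int:
        return self.tapA.shape[0]

    def n_on(self, threshold: int = 200) -> np.ndarray:
        """Number of matrix-ON cells (TapA >= threshold) at each time."""
        return (self.tapA >= threshold).sum(axis=0)

    def n_off(self, threshold: int = 200) -> np.ndarray:
        return self.n_cells - self.n_on(threshold)

    def summary_to_csv(self, path, threshold: int = 200) -> None:
        """Write the per-time N_ON / N_OFF counts to CSV."""
        n_on = self.n_on(threshold)
        arr = np.column_stack([self.times, n_on, self.n_cells - n_on])
        np.savetxt(path, arr, delimiter=",",
                   header="time_h,n_on,n_off", comments="")


def run_ensemble(model: SSAModel, inp, n_cells: int,
                 seed_base: int, duration: float = 40.0,
                 initially_on: bool = False,
                 burn_in_input=None, burn_in_duration: float = 60.0,
                 record_dt: float = 0.1) -> EnsembleResult:
    """Ensemble of independent cells, each from its own burn-in.

    Cell k uses seed ``seed_base + k`` for its burn-in and
    ``seed_base + k + 10**6`` for the main run.  The burn-in input
    defaults to 0 (initially OFF) or a saturating constant (initially ON).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if burn_in_input is None:
        burn_in_input = 3.0 if initially_on else 0.0
    n_rec = int(math.floor(duration / record_dt)) + 1
    tap = np.zeros((n_cells, n_rec), dtype=np.int64)
    times = np.arange(n_rec) * record_dt
    for k in range(n_cells):
        y0 = burn_in(model, burn_in_input, seed_base + k,
                     duration=burn_in_duration)
        _, rec, _ = gillespie_simulate(model, inp, duration,
                                       seed_base + k + 1_000_000, y0,
                                       record_dt)
        tap[k] = rec
    return EnsembleResult(times, tap, seed_base, initially_on)


def stochastic_cycle_ensemble(n_cells: int, seed_base: int,
                              g_mean: float = 0.4,
                              duration: float = 40.0,
                              cv: float = 0.1,
                              params: BiofilmParams | None = None,
                              ssa: SSAParams | None = None,
                              phos_params=None,
                              initially_on: bool = False,
                              n_pulse_grid: int = 25,
                              record_dt: float = 0.1) -> EnsembleResult:
    """Ensemble with stochastic cell-cycle lengths and binomial division.

    Per cell and cycle: tau_cyc ~ Normal(ln2/g_mean, cv*ln2/g_mean),
    truncated at 0.2 tau; the cycle's Spo0A~P input is the natural pulse
    regenerated at g = ln2/tau_cyc (nearest neighbour on a precomputed
    pulse library); at division every molecular count is partitioned
    Binomial(n, 1/2) and one daughter is followed.  Promoters are reset
    to the free state (bound regulators are released first by the
    partitioning of the complexed species... the single promoter copy
    itself is inherited free).
    """
    from .phosphorelay import PhosphorelayParams, periodic_pulse

    params = params or BiofilmParams.default()
    ssa = ssa or SSAParams.default()
    phos_params = phos_params or PhosphorelayParams.default()
    tau_mean = math.log(2) / g_mean
    # pulse library over ±4 sd of cycle lengths
    taus = np.linspace(max(tau_mean * (1 - 4 * cv), 0.2 * tau_mean),
                       tau_mean * (1 + 4 * cv), n_pulse_grid)
    library = []
    for tau in taus:
        g = math.log(2) / tau
        library.append(periodic_pulse(phos_params, timing_from_growth(
            g, allow_overlap=True)))
    models = {tau: build_matrix_ssa(params, ssa, timing_from_growth(
        math.log(2) / tau, allow_overlap=True)) for tau in taus}

    n_rec = int(math.floor(duration / record_dt)) + 1
    tap = np.zeros((n_cells, n_rec), dtype=np.int64)
    times = np.arange(n_rec) * record_dt
    prom_idx = [_IDX["PI_off"], _IDX["PI_on"], _IDX["PI_lock"],
                _IDX["PL_free"], _IDX["PL_rep"],
                _IDX["PT_free"], _IDX["PT_rep"]]
    for k in range(n_cells):
        rng = np.random.default_rng(seed_base + k)
        model0 = models[taus[n_pulse_grid // 2]]
        y = burn_in(model0, 3.0 if initially_on else 0.0, seed_base + k)
        t_now = 0.0
        rec_filled = 0
        while t_now < duration - 1e-9:
            tau = float(rng.normal(tau_mean, cv * tau_mean))
            tau = max(tau, 0.2 * tau_mean)
            j = int(np.argmin(np.abs(taus - tau)))
            model = models[taus[j]]
            seg = min(tau, duration - t_now)
            _, rec, y_end = gillespie_simulate(
                model, library[j], seg,
                int(rng.integers(0, 2**31 - 1)), y, record_dt)
            n_seg = rec.shape[0]
            hi = min(rec_filled + n_seg, n_rec)
            tap[k, rec_filled:hi] = rec[:hi - rec_filled]
            rec_filled = hi
            t_now += seg
            if t_now >= duration - 1e-9:
                break
            # division: bound regulators return to the free pool, then all
            # molecular counts are partitioned binomially; the single
            # promoter copy per gene is inherited free
            y = y_end.copy()
            y[_IDX["SinR_T"]] += y[_IDX["PL_rep"]] + y[_IDX["PT_rep"]]
            for s in range(len(SSA_SPECIES)):
                if s in prom_idx:
                    continue
                y[s] = rng.binomial(y[s], 0.5)
            y[_IDX["PI_off"]], y[_IDX["PI_on"]], y[_IDX["PI_lock"]] = 1, 0, 0
            y[_IDX["PL_free"]], y[_IDX["PL_rep"]] = 1, 0
            y[_IDX["PT_free"]], y[_IDX["PT_rep"]] = 1, 0
    return EnsembleResult(times, tap, seed_base, initially_on)
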