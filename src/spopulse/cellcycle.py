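"""Cell-cycle arithmetic and gene-dosage functions.

In *B. subtilis*, the DNA replication period shortens only weakly as growth
slows, while the cell cycle lengthens in proportion to 1/g.  The replication
period is modelled empirically as

    tau_rep(g) = 0.78 + 0.15 / g        [h]

and the cell-cycle length follows from balanced exponential growth,

    tau_cyc(g) = ln(2) / g              [h].

A gene at fractional chromosomal position ``p`` (0 at *oriC*, 1 at the
terminus) is replicated at time ``p * tau_rep`` into the cycle, at which
point its copy number steps from 1 to 2; it resets to 1 at division.  The
population-average copy number of such a gene is

    n(p) = 2 ** (1 - tau_rep * p / tau_cyc),

which interpolates between 2 (*oriC*-proximal) and 2**(1 - tau_rep/tau_cyc)
(terminus-proximal).  Cell size enters production rates through the
empirical size factor F(g) = a * exp(b*g) + c.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CycleTiming",
    "GenePosition",
    "SizeFactorParams",
    "OverlappingReplicationError",
    "timing_from_growth",
    "size_factor",
    "discrete_copy_number",
    "average_copy_number",
]


class OverlappingReplicationError(ValueError):
    """Raised when tau_rep >= tau_cyc (overlapping replication rounds)."""


@dataclass(frozen=True)
class CycleTiming:
    """Growth rate with derived replication / cycle / post-replication periods.

    Parameters
    ----------
    growth_rate : float
        Specific growth rate g in 1/h.  Must be positive.
    tau_rep : float
        DNA replication period in h.
    tau_cyc : float
        Cell-cycle length in h (ln 2 / g for the natural cycle).
    allow_overlap : bool
        If True, permit tau_rep >= tau_cyc.  Overlapping replication rounds
        are not modelled mechanistically; the dosage ratio is simply capped
        at 1:2 for the whole cycle.
    """

    growth_rate: float
    tau_rep: float
    tau_cyc: float
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        if not (self.growth_rate > 0):
            raise ValueError(f"growth rate must be positive, got {self.growth_rate}")
        if not (self.tau_rep > 0):
            raise ValueError(f"tau_rep must be positive, got {self.tau_rep}")
        if not (self.tau_cyc > 0):
            raise ValueError(f"tau_cyc must be positive, got {self.tau_cyc}")
        if self.tau_rep >= self.tau_cyc and not self.allow_overlap:
            raise OverlappingReplicationError(
                f"tau_rep = {self.tau_rep:.3f} h >= tau_cyc = {self.tau_cyc:.3f} h: "
                "overlapping replication rounds are not modelled "
                "(pass allow_overlap=True to cap the dosage ratio at 1:2)"
            )

    @property
    def tau_post(self) -> float:
        """Post-replication period tau_cyc - tau_rep in h (can be <= 0 only with overlap)."""
        return self.tau_cyc - self.tau_rep

    def with_overrides(self, tau_rep: float | None = None,
                       tau_post: float | None = None) -> "CycleTiming":
        """Return a copy with tau_rep and/or tau_post replaced (tau_cyc adjusts)."""
        new_rep = self.tau_rep if tau_rep is None else tau_rep
        new_post = self.tau_post if tau_post is None else tau_post
        return CycleTiming(self.growth_rate, new_rep, new_rep + new_post,
                           allow_overlap=self.allow_overlap)


@dataclass(frozen=True)
class GenePosition:
    """Fractional chromosomal position relative to oriC.

    ``p = 0`` is *oriC*-proximal (replicated at the start of the replication
    period, copy number 2 essentially always); ``p = 1`` is terminus-proximal
    (replicated at the end of the replication period).
    """

    p: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"gene position p must lie in [0, 1], got {self.p}")

    def replication_offset(self, timing: CycleTiming) -> float:
        """Time within the cycle at which the copy number doubles (h)."""
        return self.p * min(timing.tau_rep, timing.tau_cyc)


@dataclass(frozen=True)
class SizeFactorParams:
    """Constants of the cell-size function F(g) = a*exp(b*g) + c (b in h)."""

    a: float = 3.5
    b: float = -math.log(2)
    c: float = 3.7


def timing_from_growth(g: float, allow_overlap: bool = False) -> CycleTiming:
    """Derive replication/cycle timing from the growth rate.

    Parameters
    ----------
    g : float
        Growth rate in 1/h; must be positive.

    Returns
    -------
    CycleTiming
        tau_rep = 0.78 + 0.15/g, tau_cyc = ln(2)/g.

    Raises
    ------
    ValueError
        If g <= 0.
    OverlappingReplicationError
        If tau_rep >= tau_cyc (g ≳ 0.63 1/h) and ``allow_overlap`` is False.
    """
    if not (g > 0) or not math.isfinite(g):
        raise ValueError(f"growth rate must be a positive finite number, got {g}")
    tau_rep = 0.78 + 0.15 / g
    tau_cyc = math.log(2) / g
    return CycleTiming(g, tau_rep, tau_cyc, allow_overlap=allow_overlap)


def size_factor(g: float, params: SizeFactorParams = SizeFactorParams()) -> float:
    """Cell-size factor F(g) = a*exp(b*g) + c, dimensionless.

    Strictly decreasing in g for a > 0, b < 0: slow-growing cells are
    modelled as transcribing more per unit concentration change.
    """
    if g < 0:
        raise ValueError(f"growth rate must be non-negative, got {g}")
    return params.a * math.exp(params.b * g) + params.c


def discrete_copy_number(t_in_cycle: float, gene: GenePosition,
                         timing: CycleTiming) -> int:
    """Copy number (1 or 2) of a gene at a given time within the cycle.

    The gene doubles at its replication offset ``p * tau_rep`` and the copy
    number resets to 1 at division.  A gene at p = 0 therefore sits at 2
    for the entire cycle.
    """
    if not (0.0 <= t_in_cycle < timing.tau_cyc):
        raise ValueError(
            f"t_in_cycle = {t_in_cycle} outside [0, tau_cyc = {timing.tau_cyc:.3f})"
        )
    return 2 if t_in_cycle >= gene.replication_offset(timing) else 1


def average_copy_number(gene: GenePosition, timing: CycleTiming) -> float:
    """Population-average copy number n = 2^(1 - tau_rep*p/tau_cyc) in [1, 2]."""
    ratio = min(timing.tau_rep / timing.tau_cyc, 1.0)
    return 2.0 ** (1.0 - ratio * gene.p)
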