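# Methods

This note records the models implemented in `spopulse`, the choices made
where the design was genuinely open, and what the shipped calibration can
and cannot be expected to show.

## Cell-cycle scaffolding

Growth enters everything through three empirical relations: the DNA
replication period `tau_rep(g) = 0.78 + 0.15/g` h, the cell-cycle length
`tau_cyc(g) = ln2/g` h, and the cell-size factor
`F(g) = 3.5 e^(−ln2·g) + 3.7` that scales all transcription. A gene at
fractional chromosomal position `p` (0 at *oriC*, 1 at the terminus)
doubles its copy number at `p·tau_rep` into the cycle and resets at
division; its population-average copy number is
`n = 2^(1 − tau_rep·p/tau_cyc)`. We use the exponential form for the
average because the linear reading would fall below one copy for large
`tau_rep·p/tau_cyc`, which is not meaningful. Overlapping replication
rounds (`tau_rep ≥ tau_cyc`, roughly g ≳ 0.63 1/h) are not modelled
mechanistically: constructors reject such timings unless an explicit
override caps the dosage ratio at 1:2.

## Phosphorelay model (the pulse generator)

Ten species (KinA, Spo0F, Spo0B, Spo0A and their phosphoforms, plus the
phosphatases Rap and Spo0E) and six delayed production-rate variables.
Transcription initiation per gene is a Hill function of [Spo0A~P] scaled
by `F(g)`; the realised production rate relaxes toward it with constant
`kdel` (≈5 min delay) and is multiplied by the gene's current discrete
copy number. The phosphotransfer chain is mass action
(KinA~P→Spo0F~P→Spo0B~P→Spo0A~P); Rap and Spo0E dephosphorylate Spo0F~P
and Spo0A~P. KinA autophosphorylation is inhibited by free Spo0F in
proportion to the Spo0F:KinA ratio (a sequestration-like readout of the
kinA:spo0F dosage balance) with Hill exponent 4.

The pulse mechanism: *spo0F* sits at the origin (2 copies throughout the
cycle), *kinA* at the terminus (1 copy until replication completes).
During replication the surplus of unphosphorylated Spo0F inhibits KinA
and [0A~P] stays low; when *kinA* doubles, the kinase — given a fast
intrinsic turnover so its concentration tracks its gene dosage within
the cycle — outruns the inhibition, the Spo0F pool shifts to its
phosphorylated form, and [0A~P] overshoots until division. A slow
Spo0A~P-induced Spo0E pool quenches the pulse on a 1–2 h timescale, so
at long cycles the signal returns to a plateau rather than staying at
its peak; this makes the cycle-averaged [0A~P] saturate (~0.3 µM) as
growth slows while the peak keeps growing.

Integration is segmented at every copy-number step and division with
LSODA (rtol 1e-8, atol 1e-10); state is carried across segments
(dilution is continuous; only copy numbers reset at division). The first
three cycles are discarded as transient by default. For long periodic
inputs we simulate ~12 cycles once and tile the last cycle
(`periodic_pulse` + `tile_cycles`); post-transient cycles agree to
better than 1e-3 of the pulse amplitude, so the tiling error is
negligible.

Under a time-varying growth schedule, a cycle ends when the integral of
g over the cycle reaches ln 2; each cycle's replication period uses g at
cycle start, while dilution and `F(g)` follow g live.

## Matrix-production network

Seven species: SinI dimer, SinR dimer, SinR tetramer, SlrR dimer, the
LR and IR sequestration complexes, and TapA as readout. Spo0A~P induces
*sinI* (Michaelis form, half-saturation `Ki`); the SinR tetramer
represses *slrR* and *tapA*; SinI and SlrR sequester the SinR dimer.
mRNA is at quasi-steady state, so each production term carries the
factor `ktran/kdegm`; the transcription/translation split is explicit so
the stochastic model can inherit it unchanged. Effective protein removal
is `kdegpro + g` (degradation plus dilution), with elevated turnover for
free SlrR (0.8 1/h), free SinI and the LR complex. SinI is produced
directly in dimer form (one fewer species; nothing downstream depends on
the monomer).

The double-negative SinR/SlrR loop makes the network bistable: matrix-ON
(SinR sequestered, TapA ≈ 2–3 µM at g = 0.2) versus matrix-OFF (SinR
free, TapA ≈ 0.1 µM). ON/OFF classification uses the geometric mean of
the two branch TapA values at the g = 0.2 reference (computed once per
parameterisation and cached).

Steady states are found by integrating ≥100 h and requiring
max |dX/dt|/(|X|+1e-9) < 1e-6, extending in 50 h blocks to at most
400 h. The deactivation-cycle search walks the 0.1 h grid of cycle
lengths from the g = 0.2 baseline; because the end-state mean TapA is
monotone in the cycle length for every scenario handled, the first OFF
grid point is located by bisection over the grid rather than a linear
sweep (identical answer, ~8 instead of ~100 integrations). Under
pulsatile input the "steady state" is a periodic orbit; we classify by
the final cycle's mean TapA once consecutive cycles agree to 1e-3.

Growth-effect toggles: the dilution effect replaces `kdegpro + g` by
`kdegpro + g0` (g0 = 0.2 1/h); the dosage effect freezes the average
copy numbers at the g = 0.2 timing. `F(g)` always follows the live
growth rate. In phase-growth scenarios (replication-only or
post-replication-only lengthening), the dilution/size growth rate is
recomputed as ln2/tau_cyc of the modified cycle so that division rate,
dilution and cell size stay mutually consistent.

## Bifurcation and threshold analysis

The constant-input threshold `MOFF(g)` is found by bisection (1e-3 µM)
on the survival of the ON branch, starting the ON side from a state deep
in the ON basin (explicitly seeded — the empty state always races to
OFF at slow growth, and at very fast growth the OFF state can lose the
race, so neither is a reliable branch constructor). Oscillatory inputs
are zero-minimum cosines `mean·(1 + cos(2πt/T))`; the threshold is the
smallest mean sustaining ON over max(200 h, 25 periods), bisected on the
mean with an auto-expanding bracket. The matched-period curve evaluates
the threshold where the oscillation period equals the cell-cycle length
(g = ln2/T, overlap allowed at T ≈ 1 h) and is summarised by nonlinear
least squares of `a·tau^b + c` (bounded, 5 jittered starts).

Because *sinI* induction saturates (`Ki` = 0.08 µM), the threshold rises
sharply with oscillation period: long low phases drain the SlrR/SinI
memory (their free forms and the LR complex turn over in ≲1 h), and the
saturating high phase cannot compensate proportionally. With the shipped
calibration the fast-oscillation limit exceeds the constant-input
threshold by a Jensen-type gap of order 10–30% (the input passes through
a concave Michaelis stage), so the T→0 curve approaches, but does not
exactly meet, the constant threshold.

## Stochastic model

The matrix network is recast with integer counts and explicit promoter
states: Spo0A~P binding/unbinding at the *sinI* promoter (the input
enters only through the binding propensity), SinR-tetramer binding at
the *slrR* and *tapA* promoters, per-gene transcription and translation,
complex formation and degradation. Rate constants derive from the
deterministic parameterisation so the macroscopic limit is exactly the
ODE system; `omega` = 250 molecules/µM maps the ON branch to ≈500 TapA
molecules, with the 200-molecule classification threshold near the
antimode of the bimodal TapA distribution. Fractional average gene
dosage scales the transcription propensities (one promoter copy per
gene; promoter-state conservation is asserted). The simulator is the
direct-method SSA, exact within each 0.005 h refresh interval of the
piecewise-constant input (interval boundaries only truncate the
exponential waiting time, valid by memorylessness); the inner loop is
numba-compiled, with an explicit integer seed per run.

Ensembles initialise every cell from its own 60 h burn-in (zero input
for matrix-OFF, saturating input for matrix-ON) with per-cell seeds
`base + index`. The cycle-stochastic variant draws each cycle length
from Normal(ln2/g, CV = 0.1) — the stated spread is read as a
coefficient of variation, matching typical *B. subtilis* cycle-length
variability — regenerates the cycle's pulse from a precomputed library
of 25 growth rates (nearest neighbour), and partitions all molecular
counts Binomial(n, 1/2) at division, returning promoter-bound regulators
to the free pool first; one daughter is followed. The optional
promoter-locking extension adds three reactions that take the *sinI*
promoter (from either the free or the bound state) into a state where
the activator cannot bind and transcription cannot occur.

## Telegraph-rate inference

The ensemble ON-fraction is fit by the two-state occupancy solution,
one (kON, kOFF) pair simultaneously against the initially-OFF and
initially-ON curves (pooled least squares, log-space Nelder–Mead with 8
starts, rates bounded to [1e-6, 10] 1/h; R² per curve against each
curve's own mean, MSE pooled). The fitting grid is 0.1 h over 40 h.
The two-state description is effective: the underlying switch dynamics
are not exactly memoryless, and no correction for that is attempted.
Threshold-robustness analysis redraws the ON threshold uniformly in
25–175% of 200 molecules and refits.

## Calibration

The rate constants in `params/*.yaml` are this package's own
calibration. Anchors held fixed during calibration: the replication/
cycle-length/size-factor laws and their constants; mRNA degradation
8.3 1/h; protein degradation 0.2 1/h with unstable SlrR at 0.8 1/h; the
chromosomal arrangement kinA terminus / spo0F origin; *slrR* origin-
proximal versus *sinR/sinI/tapA* terminus-proximal. The free constants
were chosen to reproduce, in order of priority: (i) one deep Spo0A~P
pulse per cycle with the trough at the end of the replication window and
amplitude growing then saturating as growth slows; (ii) bistability of
the matrix network at g = 0.2 with a deactivation threshold near 0.1 µM
and >10× separated TapA branches; (iii) a full-model cell-cycle
deactivation threshold near 3.9 h with the growth-effect decomposition
ordered full < no-dilution < no-dosage < neither < constant-input;
(iv) a matched-period threshold curve well fit by a power law with
exponent near 2.6; (v) stochastic matrix switching at g = 0.4 on the
hours timescale with pulsing lowering kON and raising kOFF.

Known shortfalls of the shipped calibration (all visible in the test
suite): the no-dilution and neither conditions deactivate later than the
reference decomposition (4.37 h and 7.67 h versus 4.0 h and 4.8 h), the
constant-input condition sits at ~1.9× rather than ~3× the full-model
threshold, and the stochastic kOFF increase under pulsing is an order of
magnitude smaller than the reference (~0.003 vs ~0.07 1/h) because the
natural-pulse trough at g = 0.4 does not fall far enough below the
deactivation threshold; and in the phase-growth comparison the
replication-only scenario deactivates slightly later (4.27 h) than the
post-replication-only scenario (3.97 h) rather than earlier, because the
slow Spo0E adaptation penalises long high phases more than long troughs. These quantities share control parameters (the
ON-state memory timescales) with the calibrated anchors above and could
not be reconciled simultaneously; the signs and orderings all agree.

## Problem sizes

Defaults chosen for routine runs: 12 settle cycles for periodic pulses;
120–400 h horizons for steady states and threshold bisections (1e-3 µM);
0.1 h grid for deactivation-cycle searches; 500–2000 cells per ensemble
arm, 40 h per cell after a 60 h burn-in; 100 threshold draws for the
robustness analysis. All are arguments, not constants.

## Limitations

The synthetic input generator produces idealised signals: exactly
periodic pulses post-transient, cosines with zero minimum, square pulse
trains. Real single-cell Spo0A~P traces carry cycle-to-cycle amplitude
noise and lineage correlations that only the cycle-stochastic ensemble
partially emulates. The kinase tier is reduced to KinA; KinB–KinE, the
kinase inhibitors, downstream sporulation commitment and spatial biofilm
structure are out of scope. Passing tests demonstrate internal
consistency of the models and reproduction of the calibrated reference
behaviour, not agreement with any particular experimental dataset.
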