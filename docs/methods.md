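# Methods

## Problem

Spontaneously beating cardiomyocytes derived from human induced
pluripotent stem cells (hiPSC-CMs) show a wide, continuous variety of
action-potential (AP) shapes, presumably because the functional expression
levels of their membrane currents differ from cell to cell.  `paceopt`
addresses the corresponding inverse problem: given one cell's spontaneous
AP waveform, estimate the whole-cell conductances `G_x = Gbar_x * sf_x` of
the underlying currents by adjusting the dimensionless scaling factors
`sf_x` of a mechanistic membrane model until the simulated waveform
matches the recording.  Because different current mixtures can produce
nearly identical APs, the package treats identifiability as a first-class
question: alongside the optimizer it provides a global MSE landscape
mapper, multi-run convergence statistics, and PCA / hyperplane analyses of
the recovered parameter ensembles.

## Forward model

The cell model (docs/FORMULATION.md) carries eleven membrane currents —
nine conductance-scaled channels (Na, CaL, ha, K1, Kr, Ks, Kur, Kto,
bNSC) and two transporters (NaK, NCX) — Hodgkin–Huxley gating, and a
five-compartment Ca system.  Intracellular Na+ and total cell Ca are
clamped to references (6.1 mM, 79 amol) by a per-cycle integral feedback
on the transporter capacities with gains 0.3 per mM and 0.008 per amol;
the correction factors `crf_NaK`, `crf_NCX` are part of the state.  This
keeps the transporter currents' time courses essentially constant while
the channel factors are varied, so the optimization estimates channel
conductances against a stationary ionic background.

At `sf = 1` the model beats with CL ≈ 1087 ms, OS ≈ +22.8 mV,
MDP ≈ −76.0 mV and APD(−20 mV) ≈ 147.8 ms — inside the observed hiPSC
bands — with a long (~0.9 s) slow diastolic depolarization carried by
I_ha, I_bNSC and the deactivating I_Kr tail against I_K1.

## Objective

`MSE = Σ (V_a − V_t)² / N` over one full cycle on the 0.1 ms grid.  The
last complete cycle of each trace is registered at its upstroke, defined
as the maximal-dV/dt instant (gated by an upward −20 mV crossing with a
−40 mV hysteresis, refined to sub-sample precision by parabolic
interpolation of the discrete derivative).  This landmark is invariant to
constant voltage offsets, so a pure 2 mV offset scores exactly 4 mV².
Cycle-length mismatch deliberately leaks into the end-of-window residual —
that is how the search feels CL errors.  Quiescent candidates (no upstroke
within 4 s, or oscillations too shallow to register one) receive a finite
penalty of 10⁴ mV².  Optional phase windows (plateau / repolarization /
SDD) exactly partition the cycle, so the full-cycle MSE is their
count-weighted mean; they are opt-in and unused by the default protocol.

## Optimizer

Plain base-point/new-point Pattern Search: for each selected factor in
roster order the candidate `BP ± stp` is evaluated and the best of the
three kept (ties prefer `+stp`; non-positive factors are rejected
unevaluated); when a full sweep brings no improvement the step contracts
by `redFct = 1/4`; the run ends when `stp < crtstp`.  Defaults
`stp0 = 0.04`, `crtstp = 2×10⁻⁵`.  The BP cost sequence is non-increasing
by construction, and the number of contractions is bounded by
`ceil(log(crtstp/stp0)/log(redFct))`, so every run terminates.  An
evaluation cache keyed by the sf vector quantized at `crtstp/10` avoids
re-simulating revisited points.  A Hooke–Jeeves pattern-move acceleration
was evaluated during development and did not improve recovery on this
model's sloppy directions, so the plain method stands.

Each cost evaluation integrates the model from the target's stored
settled state for a fixed number of cycles (12 by default) and scores the
last cycle.  The fixed count makes the cost a continuous, deterministic
function of the factors; at the true factors the trajectory simply stays
on the target's limit cycle, so the cost minimum sits at the truth with a
numerical floor near 10⁻⁵ mV².  (Two alternatives were rejected after
measurement: chaining evaluations from the previous final state makes the
cost path-dependent and noisy, and stability-gated early stopping makes
the cycle count — and hence the cost — discontinuous in the factors;
both caused premature stalls.)

## Multi-run (orp) protocol and statistics

A recovery experiment draws `n_runs` initial sets by uniformly
randomizing the true factors by ±`range_pct` (independent per current,
per run, child-seeded from one root seed), runs Pattern Search from each,
and summarizes the `k = 20` smallest-final-MSE runs: per-factor mean and
standard error (SD/√k), mean final log10(MSE), and the final Na_i and
Ca_tot.  Individual runs frequently stall at intermediate MSE on sloppy
valley floors; selection by final MSE is what makes the top-k statistics
sharp.  A constrained variant freezes chosen factors at given values and
searches the rest.

## Identifiability analytics

* Landscape: log-uniform sf draws over wide ranges (default 1/10–10×),
  scored against a fixed target; per-axis minimum-MSE envelopes over
  log-spaced bins; interior envelope minima detected by prominence (0.2
  log10 units) via `scipy.signal.find_peaks`.  The baseline point is
  injected deterministically so the global minimum is always present.
* PCA by the variance-maximizing deflation scheme (power iteration on the
  deflated scatter matrix, explicit re-orthogonalization, sign fixed so
  each loading's largest entry is positive), cross-checked against the
  eigendecomposition in tests.  Inputs are centered, not scaled: the
  factors share units.
* Plane fits: total-least-squares normal (unit length, so the printed
  equation's coefficients are comparable across fits) plus an ordinary
  multiple-regression R² with a designated response (default: the
  best-explained variable), and a 2-D composite replot R² that sums the
  inward-current terms against the outward one.

In this formulation the identifiability structure mirrors what is
expected physiologically: the pairwise-compensation scan shows strong
degeneracy among the SDD currents (ha–K1, ha–bNSC, K1–bNSC residual
ratios 0.01–0.10) — these currents trade off along a near-plane while the
waveform barely changes — while Kr and CaL are sharply identified.

## Default experiment scales

Chosen once as the package's desk-scale protocol:

* Target generation: settle ≥250 cycles until the cycle length is stable
  to ~3×10⁻⁶ (relative, over 4 cycles, scaled with dt²) and the ion
  setpoints are met to 5×10⁻⁵ mM / 5×10⁻⁴ amol; the stored final state
  defines the reference limit cycle.
* Recovery acceptance experiment: 4 selected currents (Kr, CaL, K1,
  bNSC — ha frozen, matching how weakly-contributing currents are left at
  default), ±10% randomization, 30 runs, top-20 statistics, integrator
  step 0.05 ms, 10 cycles per evaluation.
* Landscape acceptance experiment: 2 free factors (Kr, bNSC), 1000
  log-uniform samples over [0.1, 10], 25 bins per axis.
* Homeostasis experiment: default step 0.02 ms, ≤100 cycles from Na_i
  perturbed ±10%.

## Integration accuracy

Fixed-step Rush–Larsen/Euler kernel (docs/FORMULATION.md).  Because
targets are generated by the same discretization as candidates, recovery
accuracy depends on determinism rather than absolute accuracy; the
absolute discretization error (vs LSODA at rtol 1e-8) is below 0.5 mV
over a cycle, and halving dt changes the aligned waveform by far less
than the objective's floor.  Coarsening dt from 0.02 to 0.05 ms shifts
the AP metrics by <0.03% and raises the evaluation floor from ~4×10⁻⁶ to
~2×10⁻⁵ mV²; the recovery experiment absorbs this because both target
and candidates share the step.

## What the synthetic data does and does not show

Targets are noise-free model outputs; recovery to <1% therefore
demonstrates the optimizer's accuracy and the model's identifiability
structure, not robustness to recording artifacts.  The fluctuation
generator (low-pass-filtered Gaussian noise of prescribed mean-square
power, 1–6 mV² typical) emulates the slow drift seen in real recordings
and raises the aligned MSE by about its power; it is used in robustness
tests only.  Real recordings additionally contain electrode drift,
capacitance transients and beat-to-beat variability that none of this
reproduces, and the true cell need not lie inside the model family at
all — conclusions about real hiPSC-CM conductances require the manual
pre-fit step that is out of scope here.

## Known limitations

* The formulation is deliberately compact: no T-type Ca current, no
  stochastic Ca release units, no ATP/phosphorylation modulation; the
  upstroke is CaL-led (nodal-like), so sf_Na is less sharply identified
  than it would be in a fast-upstroke ventricular model.
* The per-cycle homeostasis update requires a beating model; in quiescent
  regimes the correction factors freeze at their floor.
* Pattern Search is a local method; the multi-run protocol with
  randomized starts is the only global element, as intended.
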