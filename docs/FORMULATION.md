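# Baseline cell formulation (`formulation_id: paceopt-hipsc-v1`)

This package's forward model is a compact Hodgkin–Huxley-style description
of a small, spontaneously depolarizing human cardiomyocyte of the
hiPSC-derived type: an immature cell with a slow diastolic depolarization
(SDD), a calcium/sodium-driven upstroke, and a maximum diastolic potential
(MDP) in the −60 to −85 mV range.  It is written from scratch for this
package; the individual building blocks follow standard published forms
(Hodgkin–Huxley first-order gating, Luo–Rudy-style Na/Ca exchanger,
saturating Na/K pump, compartmental Ca cycling with rapid linear
buffering) with parameters tuned so that the default model satisfies the
contract required by the recovery experiments:

1. the membrane current is exactly the eleven-term roster
   `I_tot = I_Na + I_CaL + I_ha + I_K1 + I_Kr + I_Ks + I_Kur + I_Kto +
   I_bNSC + I_NaK + I_NCX`;
2. `dV_m/dt = -I_tot/C_m`; every channel current has the form
   `sf_x * Gbar_x * pO * (V_m - E_x)`; every gate obeys
   `dpO/dt = alpha(V)(1-pO) - beta(V) pO` with non-negative rates;
3. at `sf = 1` the model beats spontaneously with CL, OS, MDP inside the
   observed hiPSC bands (CL 239.5–1326 ms, OS 13.8–33 mV, MDP −87.4 to
   −61.5 mV) and a long SDD;
4. the intracellular-ion homeostasis feedback holds `[Na+]_i` at 6.1 mM
   and total cell Ca at 79 amol.

Units throughout: mV, ms, pA, nS, pF, mM, pL, amol.

## Membrane currents

| current | gates (pO)        | reversal            | Gbar / scale        | role |
|---------|-------------------|---------------------|---------------------|------|
| I_Na    | m^3 h             | Nernst(Na)          | 24 nS               | upstroke acceleration, late-SDD inward |
| I_CaL   | d f               | fixed +50 mV        | 2.6 nS              | upstroke and plateau |
| I_ha    | y                 | fixed −30 mV        | 0.7 nS              | hyperpolarization-activated SDD driver |
| I_K1    | instantaneous rectification | Nernst(K) | 1.3 nS              | MDP, early SDD |
| I_Kr    | pa · pi           | Nernst(K)           | 0.9 nS              | repolarization, deactivating tail in SDD |
| I_Ks    | n                 | Nernst(K)           | 0.25 nS             | slow plateau K current |
| I_Kur   | r                 | Nernst(K)           | 0.18 nS             | sustained outward plateau current |
| I_Kto   | q s               | Nernst(K)           | 0.15 nS             | transient outward (endo-type, small) |
| I_bNSC  | pO ≡ 1            | fixed 0 mV          | 0.12 nS             | time-independent background cation current |
| I_NaK   | —                 | cycle               | maxI 4100 pA        | 3Na/2K pump |
| I_NCX   | —                 | cycle               | scale 2200 pA       | 3Na/1Ca exchange |

Gate kinetics are expressed through Boltzmann steady states `x_inf(V)` and
bell-shaped time constants `tau_x(V)`; rates are `alpha = x_inf/tau`,
`beta = (1-x_inf)/tau` (both non-negative by construction).  The numbers
live in `paceopt.model.formulation`.  Two channels are not gated by
ODE states: I_K1 uses an instantaneous rectification factor
`1/(1+exp((V-(E_K+8))/10))` (the classic inward-rectifier block by
intracellular Mg2+/polyamines is fast on our timescales), and I_bNSC is a
time-independent net background current.

The Na/K pump is `I_NaK = crf_NaK * maxI_NaK * (Na_i/(Na_i+45))^3 * fV(V)`
with `fV = 1/(1+0.2 exp(-V/40))`.  The cubic Na dependence matters: with
the fixed per-cycle feedback gain of the homeostasis controller (below), a
shallower pump Na sensitivity leaves the discrete Na control loop
marginally unstable (a persistent ~0.1 ms cycle-length ripple with a
~50-cycle period), which floors the waveform MSE far above the optimizer's
resolution.  The cubic form, together with a cytosolic volume small
enough that the per-cycle Na turnover is a sizeable fraction of the Na
pool, provides the self-damping that makes the limit cycle
asymptotically stable and lets a +/-10% Na_i perturbation decay to the
setpoint within 100 cycles.

The exchanger is the standard single-energy-barrier form
`I_NCX = crf_NCX * k_NCX * (e1 Na_i^3 Ca_o - e2 Na_o^3 Ca_iz) / denom`
with `e1 = exp(gamma V/RT)`, `e2 = exp((gamma-1)V/RT)`, gamma 0.35,
Km_Na 87.5 mM, Km_Ca 1.38 mM, ksat 0.1.

## Intracellular ions and Ca compartments

`Na_i` and `K_i` evolve from the integrated membrane fluxes (3:2
stoichiometry for the pump, 3:1 for NCX; the mixed cation currents I_ha
and I_bNSC split 50/50 and 70/30 between Na and K).

Total Ca is tracked in five compartments — junctional cleft (jnc),
intermediate zone (iz), bulk cytosol (blk), SR uptake (SRup) and SR
release (SRrl) — with fixed volumes (0.01, 0.10, 0.50, 0.06, 0.015 pL)
and rapid linear buffering (free = total/beta, beta = 12, 20, 50, 1, 15).
Fluxes: L-type Ca influx into jnc; passive jnc→iz→blk diffusion; a Hill
SERCA uptake blk→SRup; SRup→SRrl transfer; a release flux SRrl→jnc gated
by the CaL activation gate (deterministic, AP-synchronized); a small
SRup→blk leak; NCX extrusion from iz.  Total cell Ca is the
volume-weighted sum over the five compartments (reported in amol).

## Homeostasis feedback

Once per detected cycle (upward −20 mV crossing):

    crf_NaK += -(6.1 mM  - Na_i)  * 0.3   [per mM]
    crf_NCX += -(79 amol - Ca_tot) * 0.008 [per amol]

The correction factors multiply maxI_NaK and the NCX scale, clamping
`Na_i` and `Ca_tot` to their references on a timescale of tens of cycles;
both are floored at 0.05 (with a warning) to avoid sign reversal in
degenerate regimes.

## Integration scheme

Fixed-step hybrid kernel (numba-compiled): Rush–Larsen exponential update
for the eleven gates from tabulated `(x_inf, exp(-dt/tau))` pairs on a
0.05 mV grid, forward Euler for V_m and the seven concentration states.
Default dt = 0.02 ms; output is decimated to the exact 0.1 ms grid the
MSE objective is defined on.  Because the recovery experiments compare
model output with model output produced by the same discretization, the
optimizer's resolution is set by determinism and limit-cycle convergence
rather than by absolute ODE accuracy; a consistency test against an
adaptive LSODA integration of the same right-hand side and a step-halving
test guard the discretization.
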