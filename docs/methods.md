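# Methods

## The models

`mirpulse` studies post-transcriptional repression by a microRNA whose
synthesis is *pulsed* rather than constant. The core is a dimensionless
mass-action model (M1) of one target RNA `R`, the free miRNA `r` and their
complex `C`:

    dR/dt = 1 − R − κ_on·r·R + κ_off·C + γβ·C
    dr/dt = σ(t) − γ·r − κ_on·r·R + κ_off·C + α·C
    dC/dt = κ_on·r·R − κ_off·C − α·C − γβ·C

Concentrations and time are scaled by the target's synthesis and
degradation rate constants, so target turnover is 1 and one time unit is
1/ln 2 ≈ 1.44 target half-lives. All parameters are *relative* kinetics:

| parameter | meaning | default range (log-uniform) |
|---|---|---|
| σ | miRNA synthesis rate relative to the target's | 10⁻² – 10² |
| γ | free-miRNA decay relative to the target's (> 0) | 10⁻² – 10² |
| κ_on, κ_off | scaled association / dissociation rates (K = κ_off/κ_on) | 10⁻¹ – 10³ / 10⁻² – 10² |
| α | target decay in complex relative to free (degrading `R` recycles `r`) | 10⁻¹ – 10² |
| β | miRNA decay in complex relative to free (degrading `r` recycles `R`) | 10⁻² – 10¹ |

The scheme has eight elementary channels (2 syntheses, 2 free decays,
binding, unbinding, 2 recycling decays) and a single positive steady state;
`steady_state_m1` finds it by reducing the equilibrium conditions to a
quadratic in `r` whose root product is ≤ 0 (hence exactly one admissible
root) and verifies the residual at 1e-10.

Model M2 adds a second target (`R2`, `C2`, synthesis δ and decay ε relative
to the first) competing for the same miRNA pool — the minimal ceRNA
setting. Its steady state reduces to one monotone scalar equation
g(r) = σ on the bracket [0, σ/γ], solved by bisection (brentq) plus Newton
polish; a damped fixed-point iteration would also work, but the bracketed
root-find cannot diverge and meets the same 1e-10 residual contract.
Setting κ_on_2 = κ_off_2 = δ = 0 reduces M2 to M1 exactly (tested to 1e-8
on trajectories and 1e-6 on fold-repression curves).

## Forcing and dose conservation

Pulsed synthesis is a square wave: σ on (nT, (n+d)T], 0 on
((n+d)T, (n+1)T], duty cycle d = 0.5 by default (ON and OFF phases of
endogenous expression pulses are typically comparable). The ON interval is
right-closed, a measure-zero convention fixed for reproducible dense
output. Averaged over whole periods the synthesis rate is σ·d regardless of
frequency, so the dose-matched constant reference is σ_const = σ·d and
pulsed-vs-constant comparisons isolate pure frequency effects. A
dose-conserving sinusoid σd·(1 − cos 2πt/T) (mean σd, minimum 0, peak 2σd)
is provided as an alternative periodic shape; its amplitude convention is
the package's own choice, constrained only by periodicity, non-negativity
and dose conservation.

## Fold repression and metrics

Over a window [0, τ], fold repression is
FR = ⟨R_basal⟩/⟨R_repressed⟩, with R_basal the miRNA-free (linear) dynamics
started from the same target initial value. τ is the time the target needs
to settle within 1 % (configurable) of its constant-synthesis steady state
— sustained over all later output samples of the monitored target (R for
M1, R1 for M2). The admissible frequency grid is f_n = n/τ, n = 1…n_max
(default 100), exactly the frequencies completing whole periods inside the
window. The window generalizes to [t_start, t_start + τ] to study
steady-state-era responses.

Curve summaries (all ratios of FR values, hence scale-invariant):

* **A** (advantage) = ∫(FR_pulse − FR_const)₊ d log f / ∫FR_pulse d log f ∈ [0,1]
* **S** (selectivity) = 1 − ∫FR_pulse d log f / [(log f_max − log f_min)·max FR_pulse] ∈ [0,1]
* **f\*** = arg max FR_pulse (ties broken toward the lowest frequency)
* **DS** = harmonic_mean(S1, S2) · (log₁₀ f*₂ − log₁₀ f*₁); the harmonic
  mean is defined as 0 when either S vanishes.

Both integrals use the log-frequency measure (trapezoid on the grid). A
linear-frequency integral against a log-span denominator would break the
[0, 1] bound of S (a flat curve would go negative whenever the f-span
exceeds the log-span), and the positive part in A's numerator is what keeps
A ≥ 0; both choices match the log-axis, area-above-the-line reading of the
metrics. The dimensional mapping f̂ = (ln 2 / t_half)·f converts grid
frequencies to 1/hours for a target of given half-life.

## Numerics

* Integration is piecewise over the square wave's switch times, restarting
  the solver at every ON/OFF edge so discontinuities never sit inside a
  step; each segment has constant σ. Switches within rounding distance of
  the window edges are merged to avoid zero-length segments.
* The segment integrator is LSODA (stiff-capable; κ_on·r can exceed unit
  turnover by orders of magnitude) with the analytic Jacobian — free miRNA
  can exceed free target by 10⁸, which defeats finite-difference Jacobians.
  If LSODA's error control destabilizes (it can, at loose tolerances on
  strongly bound states), the segment is retried with BDF.
* Tolerances default to rtol 1e-8 / atol 1e-10 with 200 dense-output points
  per period (per unit time for constant forcing). Sweeps use a documented
  fast profile (rtol 1e-6 / atol 1e-9, 60 points per period,
  `FAST_SOLVER`); metrics move by < 5·10⁻⁴ relative between the two.
* Undershoots beyond −1e-9 (−1e-8 in the fast profile, matching its atol)
  abort a run as a positivity violation; smaller undershoot is clamped to 0
  as solver noise.
* The basal reference is the closed-form solution of the linear basal ODE,
  sampled on the repressed run's output grid and averaged with the same
  trapezoid rule, so quadrature bias cancels in the FR ratio (an identical
  pair gives FR = 1 to solver precision).
* Default initial condition is the all-zero state (nothing expressed);
  scenario studies override it, e.g. the initial-condition scan spans
  R0 ∈ [0, 1] and r0 ∈ [0, σ/γ] (σ the pulse amplitude, so the upper corner
  is the miRNA's maximal interaction-free level).

## Sensitivity analysis

Parameter sets are drawn by Latin Hypercube sampling, log-uniform per
dimension (one draw per equal-probability log₁₀ stratum), seeded and
reproducible bitwise. Every sample gets its own equilibration window τ from
its own σ_const. Failed rows (solver failure, degenerate equilibration) are
excluded with a logged count; a sweep is marked valid only if ≥ 95 % of
rows survive. PRCC is computed from the precision matrix of the
rank-transformed columns, falling back to explicit residual regressions
when ranks are collinear; it is invariant under strictly monotone
transforms of any input. "Mean range values" in grid scans are geometric
means of the bounds — the median of a log-uniform draw.

The default ranges (table above, shipped as `data/default_ranges.yaml`) are
the package's own choice of biologically plausible relative kinetics,
centred on equimolar synthesis and comparable half-lives. Sensitivity
*rankings* conditioned on ranges this wide need not transfer to narrower
experimental regimes: in particular, with δ and ε both spanning four
decades, the competitor-abundance interplay (level δ/ε) dominates some
partial correlations — locally (all else at medians) the first target's
advantage falls monotonically with ε, yet its global PRCC over these ranges
is positive, and the DS–K₂/K₁ correlation is likewise conditioning-
sensitive. Studies with their own kinetic estimates should supply their own
ranges via config.

## What the synthetic inputs do and do not emulate

All inputs are synthetic by construction (kinetic parameter draws, forcing
signals, initial conditions); there is no measurement noise, no
stochasticity in molecule numbers, no cell-to-cell variability, and the
forcing is perfectly periodic. Passing tests therefore demonstrate the
deterministic frequency-response structure of the mass-action model, not
robustness to biological noise, bursty transcription, or upstream resource
competition.

## Problem sizes

Published-scale sweeps of this kind use ~10⁴ LHS samples on a 100-point
frequency grid; one sample costs ~10² stiff ODE solves. Package defaults
for quick, reproducible runs are 10²–10³ samples on a 25-point grid (PRCC
standard errors ≈ 1/√n ≈ 0.03–0.1, ample for signs and rankings);
`scripts/acceptance.py` uses 600 (M1) and 250 (M2 studies) samples. All
sizes are arguments, so full-scale runs are one flag away.

## Known limitations

* Deterministic ODEs only — no Gillespie/noise analysis, no protein layer,
  no feed-forward-loop variants.
* The equilibration time is resolved to the dense-output grid (~τ/4000),
  not to machine precision; the frequency grid inherits that resolution.
* PRCC is a rank-linear partial measure: strongly non-monotone or
  interaction-driven effects (e.g. the σ–γ trade-off visible in pairwise
  grid scans) are summarized only coarsely.
* DS compares both targets on the *first* target's window; metrics for the
  second target in its own window require a separate run with the roles
  exchanged.
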