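# mirpulse

Does it matter whether a microRNA is produced in pulses rather than at a
steady rate? `mirpulse` answers this for minimal miRNA–target networks: it
implements dimensionless mass-action models of one (M1) or two competing
(M2) target RNAs titrated by a shared miRNA, drives them with
dose-conserving periodic synthesis, and quantifies how repression depends
on pulse frequency. It is a library for systems biologists studying
pulsatile post-transcriptional regulation (circadian or developmental
miRNAs, synthetic oscillators), with a thin CLI for one-command runs.

## The model and metrics

Model M1 (scaled so target synthesis and decay are 1; one time unit =
1/ln 2 ≈ 1.44 target half-lives):

    dR/dt = 1 − R − κ_on rR + κ_off C + γβC
    dr/dt = σ(t) − γr − κ_on rR + κ_off C + αC
    dC/dt = κ_on rR − κ_off C − αC − γβC

σ(t) is either a square wave (amplitude σ, duty d = 0.5, period T) or the
dose-matched constant σ_const = σ·d, so comparisons isolate frequency, not
dose. Over the window [0, τ] (τ = the target's equilibration time under
constant synthesis) the fold repression is FR = ⟨R_basal⟩/⟨R_repressed⟩,
computed on the admissible frequency grid f_n = n/τ. The FR_pulse(f) curve
is summarized by:

* **advantage** A ∈ [0,1] — area of FR_pulse above FR_const (log-f measure),
  the repressive benefit of pulsing;
* **selectivity** S ∈ [0,1] — band-pass sharpness of the curve;
* **preferred frequency** f\* — arg max FR_pulse;
* **differential selectivity** DS = harm_mean(S¹,S²)·(log₁₀f\*² − log₁₀f\*¹)
  for two competing targets (model M2) — detects mutually exclusive
  frequency-driven repression.

Global sensitivity uses log-uniform Latin Hypercube sampling and partial
rank correlation coefficients (PRCC); local structure comes from pairwise
log-spaced parameter grids and initial-condition scans. See
`docs/methods.md` for assumptions, numerics and limitations.

## Worked example

```bash
python examples/frequency_response.py
```

prints (median kinetics: σ = 1, κ_on = 10, κ_off = 1, α = 10^0.5,
β = 10^−0.5, γ = 1):

```
observation window tau = 5.500 (time for the target to equilibrate under constant synthesis)
FR_const = 2.8142
FR_pulse ranges from 2.8223 to 3.1176 over f in [0.1818, 18.1818]
advantage A = 0.0406   (fraction of the FR_pulse area lying above FR_const: pulsing represses more than constant synthesis)
selectivity S = 0.0591   (band-pass sharpness of the curve)
preferred frequency f* = 0.3636
  for a target with half-life  0.5 h, f* corresponds to 0.5041 1/h (period 2.0 h)
  for a target with half-life  4.0 h, f* corresponds to 0.0630 1/h (period 15.9 h)
  for a target with half-life 24.0 h, f* corresponds to 0.0105 1/h (period 95.2 h)
```

Reading: at typical relative kinetics, pulsed synthesis beats the
dose-equivalent constant synthesis at low frequencies (FR 3.12 vs 2.81, a
band-pass response peaking at f\* = 0.36, i.e. one pulse every ~2.8
half-lives of the target); at high frequency the curve collapses onto
FR_const. The half-life mapping shows which real timescales that preference
corresponds to — for a 4 h mRNA the preferred period is ~16 h, in the range
of circadian-like forcing.

Other examples: `sensitivity_m1.py` (LHS + PRCC parameter ranking),
`competitor_crosstalk.py` (a ceRNA competitor reshapes its neighbour's
response), `differential_selectivity.py` (exclusive frequency-driven
regulation of two targets), `initial_conditions.py` (transient-state
dependence on starting concentrations).

The same computations are available as shell commands with YAML configs:

```bash
mirpulse simulate --config cfg.yaml --out-dir out/    # trajectory CSV + sidecar
mirpulse freqresp --config cfg.yaml                   # FR curve + metrics
mirpulse sample / prcc / scan / icscan / ds           # sensitivity studies
```

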