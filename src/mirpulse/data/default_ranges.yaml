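# Default log-uniform sampling ranges for the dimensionless kinetic
# parameters (lo, hi), one order-of-magnitude span per side of a
# biologically typical midpoint. All parameters are ratios of miRNA and
# target rate constants, so ranges are centred near 1 (equimolar synthesis,
# comparable half-lives) and span the orders of magnitude covered by
# published miRNA/target kinetics: binding can be much faster than target
# turnover (kappa_on up to 1e3), miRNA decay in complex is typically slow
# (recycling; beta down to 1e-2). Replace with study-specific ranges via a
# config file to reproduce a particular experimental estimate.
M1:
  sigma: [1.0e-2, 1.0e+2]
  kappa_on: [1.0e-1, 1.0e+3]
  kappa_off: [1.0e-2, 1.0e+2]
  alpha: [1.0e-1, 1.0e+2]
  beta: [1.0e-2, 1.0e+1]
  gamma: [1.0e-2, 1.0e+2]
M2:
  sigma: [1.0e-2, 1.0e+2]
  gamma: [1.0e-2, 1.0e+2]
  kappa_on_1: [1.0e-1, 1.0e+3]
  kappa_off_1: [1.0e-2, 1.0e+2]
  alpha_1: [1.0e-1, 1.0e+2]
  beta_1: [1.0e-2, 1.0e+1]
  kappa_on_2: [1.0e-1, 1.0e+3]
  kappa_off_2: [1.0e-2, 1.0e+2]
  alpha_2: [1.0e-1, 1.0e+2]
  beta_2: [1.0e-2, 1.0e+1]
  delta: [1.0e-2, 1.0e+2]
  epsilon: [1.0e-2, 1.0e+2]
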