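"""Can one miRNA repress two targets at mutually exclusive frequencies?

The differential selectivity DS combines both targets' band-pass sharpness
(harmonic mean of S1, S2) with the log-distance between their preferred
frequencies: |DS| is large only when both targets are selective AND tuned
to different pulse rates. Here the two targets' binding affinities are
pulled apart via kappa_on_2 while everything else stays at median kinetics.
"""

from mirpulse import differential_selectivity, frequency_response_pair, metric_set
from mirpulse.sampling import ParameterRanges

ranges = ParameterRanges.m2_full()
medians = ranges.geometric_medians()

print(" kappa_on_2    DS       S1      S2     f*1     f*2")
for kappa_on_2 in (0.3, 10.0, 1000.0):
    params = ranges.make_params({**medians, "kappa_on_2": kappa_on_2})
    r1, r2 = frequency_response_pair(params, n_max=25)
    ds = differential_selectivity(r1, r2)
    m1, m2 = metric_set(r1), metric_set(r2)
    print(f"  {kappa_on_2:>8}  {ds:+.4f}  {m1.selectivity:.4f}  {m2.selectivity:.4f}"
          f"  {m1.preferred_frequency:.3f}  {m2.preferred_frequency:.3f}")

print(
    "\nReading: with equal affinities (kappa_on_2 = kappa_on_1 = 10) the two\n"
    "targets share one preferred frequency and DS = 0; skewing the affinity\n"
    "separates their preferred frequencies, so pulse rate alone can choose\n"
    "which target is repressed."
)
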