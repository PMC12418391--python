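"""Which kinetic parameters control frequency-dependent repression?

Draws a small log-uniform Latin Hypercube over the single-target model's
parameter space, evaluates the advantage A, selectivity S and preferred
frequency f* for every draw, and ranks parameters by partial rank
correlation (PRCC). A production run would use thousands of samples; 150
suffice to see the dominant structure.
"""

from mirpulse.sampling import ParameterRanges, evaluate_samples, lhs_loguniform, prcc_table

ranges = ParameterRanges.m1()
samples = lhs_loguniform(ranges, 150, seed=7)
results = evaluate_samples(samples, ranges)
print(f"evaluated {len(results)} parameter sets "
      f"({results.attrs['n_excluded']} excluded)")

table = prcc_table(results, list(ranges.sampled_names), ["A", "S", "f_star"])
print("\nPRCC (rows: metrics, columns: parameters):")
print(table.round(2).to_string())

print(
    "\nReading: the miRNA/target decay ratio gamma dominates the preferred\n"
    "frequency (unstable miRNAs need fast pulsing to accumulate), while the\n"
    "advantage of pulsing rises with in-complex target decay alpha and the\n"
    "binding rate kappa_on, and falls with gamma."
)
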