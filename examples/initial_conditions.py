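"""Frequency preference depends on where the system starts.

The fold-repression window covers the target's transient, so initial
concentrations matter. This scan varies the initial target level R0 in
[0, 1] and the initial miRNA level r0 in [0, sigma/gamma]; the corners are
the canonical scenarios: (i) both from zero, (ii) pre-expressed target,
(iii) pre-accumulated miRNA, (iv) both pre-expressed.
"""

from mirpulse.sampling import ParameterRanges, initial_condition_scan

params = ParameterRanges.m1().median_params()
scan = initial_condition_scan(params, resolution=3, n_max=25)

print(scan.round(4).to_string(index=False))
print(
    "\nReading: advantage A and selectivity S are largest when the target is\n"
    "already expressed (R0 = 1) and the miRNA starts from zero, and smallest\n"
    "when the miRNA pool is pre-loaded (r0 = sigma/gamma) — a pre-existing\n"
    "regulator erases the benefit of pulsed over constant synthesis."
)
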