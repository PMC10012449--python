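"""Intensity-to-M-value preprocessing with the probe-level QC filters.

Builds a small synthetic intensity table (with deliberately failing probes,
chrY probes and SNP-overlapping probes), then runs the full preprocessing
chain: detection-p filter, beta = M/(M+U+100), chrY/SNP filters, and the
logit-base-2 M-value transform.
"""
import smokewas as sw

cohort = sw.generate_cohort(34, seed=1)
my = sw.generate_methylome(cohort, n_probes=2_000, n_cell_types=3,
                           noise_sd=0.1, seed=2)

beta, mvalues, dropped = sw.preprocess_pipeline(my.intensities, my.annotation)

print(f"input probes: {my.intensities.n_probes}")
print("dropped per reason:", dropped.reason.value_counts().to_dict())
print(f"kept probes: {len(mvalues.values)}")
print()
# A probe is dropped when detection p > 0.01 in more than 5% of samples
# (with 34 samples that means 2 or more failing samples); chrY probes go
# because the cohort is all-female, SNP-overlap probes because genetic
# variation confounds their methylation signal.  chrX probes stay.
print("beta values are bounded in [0, 1):",
      float(beta.values.min().min()), "-", float(beta.values.max().max()))
print("M-values are unbounded logits:",
      round(float(mvalues.values.min().min()), 2), "-",
      round(float(mvalues.values.max().max()), 2))
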