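"""Vicinity-based replication of discovery CpGs in an external study.

Half of the discovery CpGs get a significant validation site planted within
5 kb; the matcher flags a CpG as replicated when a same-chromosome site with
q < 0.05 lies within the window.
"""
import smokewas as sw
from smokewas.synthdata import generate_validation_table

cohort = sw.generate_cohort(34, seed=11)
my = sw.generate_methylome(cohort, 500, seed=12)
discovery = my.annotation.head(30)[["probe_id", "chromosome", "position"]]

validation, planted = generate_validation_table(
    discovery, fraction_validated=0.5, n_background=500, seed=13)

result = sw.vicinity_match(discovery, validation, window=5_000, q_threshold=0.05)

n = len(result.summary)
v = int(result.summary.validated.sum())
print(f"validated: {v}/{n} discovery CpGs "
      f"(planted as replicable: {len(planted)})")
print()
print(result.summary.head(8).to_string(index=False))
# best_q is the smallest q among in-window sites; 'validated' requires both
# distance <= 5 kb and q < 0.05, so a nearby non-significant site is listed
# as a match but does not validate the CpG.
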