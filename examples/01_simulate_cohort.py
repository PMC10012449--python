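"""Simulate a study-like donor cohort and inspect its covariates.

Generates 34 female blood donors with ages, lifetime cigarette counts and
ex-vivo IC50 values drawn from the default study-calibrated distributions,
then prints the summaries a cohort table (Table-1 style) would report.
"""
import smokewas as sw

cohort = sw.generate_cohort(34, seed=1)

print(cohort.head())
print()
print(f"age range:          {cohort.age.min()}-{cohort.age.max()} years")
print(f"cigarettes (median [range]): {int(cohort.cigarettes_total.median())} "
      f"[{cohort.cigarettes_total.min()}-{cohort.cigarettes_total.max()}]")
print(f"IC50 uM (median [range]):    {cohort.ic50.median():.2f} "
      f"[{cohort.ic50.min():.3f}-{cohort.ic50.max():.2f}]")
print(f"smoker classes:     {cohort.smoker_class.value_counts().to_dict()}")
# The IC50 spread is what the downstream interaction model tries to explain:
# a >100-fold difference in drug sensitivity between donors.
print(f"IC50 fold spread:   {cohort.ic50.max() / cohort.ic50.min():.0f}x")
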