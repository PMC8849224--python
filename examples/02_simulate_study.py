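"""Simulate the full three-condition study for a small cohort.

Builds the 10-day thrice-daily dosing schedules, samples the day-10
11-point saliva grid, adds 10% assay noise with LLOQ censoring, and prints
the tidy per-sample table.
"""

from xanpk import generate_cohort, simulate_study

cohort = generate_cohort(n=4, seed=11)
profiles = simulate_study(cohort, noise_cv=0.1, seed=11)

print(profiles.head(11).round(3).to_string(index=False))
print(f"\n{len(profiles)} samples: 4 subjects x 3 conditions x 2 analytes x 11 times")
print(f"censored (below LLOQ): {int(profiles['censored'].sum())} "
      "(all placebo samples plus late deprivation caffeine)")
caf = profiles.query("condition == 'caffeine' and analyte == 'caffeine'")
print(f"day-10 caffeine Cmax range across subjects: "
      f"{caf.groupby('subject_id')['conc_ug_ml'].max().min():.2f}-"
      f"{caf.groupby('subject_id')['conc_ug_ml'].max().max():.2f} ug/ml")
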