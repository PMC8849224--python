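"""Pointwise caffeine-vs-placebo contrasts over the sampling grid.

Paired t-tests at each of the 11 grid points with BH correction across the
grid: which sampling times show levels elevated above placebo?
"""

import pandas as pd

from xanpk import generate_cohort, pointwise_contrast, simulate_study

cohort = generate_cohort(n=20, seed=1)
profiles = simulate_study(cohort, noise_cv=0.1, seed=1)

sub = profiles.query("analyte == 'caffeine'")
a = sub.query("condition == 'caffeine'").pivot(
    index="subject_id", columns="time_h", values="conc_ug_ml")
b = sub.query("condition == 'placebo'").pivot(
    index="subject_id", columns="time_h", values="conc_ug_ml")
labels = (sub.query("condition == 'caffeine'")
          .drop_duplicates("time_h").sort_values("time_h")
          ["time_after_last_dose_h"].to_numpy())

res = pointwise_contrast(a.to_numpy(), b.loc[a.index, a.columns].to_numpy(), labels)
out = pd.DataFrame([r.__dict__ for r in res])
print(out.round(4).to_string(index=False))
print("\nEvery grid point — including the pre-dose baseline (-7.25 h, the "
      "overnight residual) — shows caffeine above placebo: daily intake "
      "never lets the level return to zero.")
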