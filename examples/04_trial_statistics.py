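"""Run the full trial statistical battery on a simulated cohort.

Generates a 167-subject two-arm cohort with the default remodeling
effects (age–diameter correlation −0.17 in the inner subfield, a mean
shift for women and for the CFH TT genotype, no treatment effect), then
prints the four report tables the analysis produces.
"""

import pandas as pd

from drusenkit import CohortParams, generate_cohort
from drusenkit.trial_stats import StatConfig, run_trial_analysis

pd.set_option("display.width", 140)

cohort = generate_cohort(CohortParams(n=167, seed=4))
report = run_trial_analysis(cohort, StatConfig())

print("— baseline arm comparisons (age, categorical covariates, drusen burden) —")
print(report["baseline"].head(8).round(3).to_string(index=False))

print("\n— adjusted arm differences on remodeling (OLS, age+gender adjusted) —")
cols = ["metric", "field", "difference", "ci_low", "ci_high", "p", "significant"]
print(report["adjusted"][cols].round(3).to_string(index=False))

print("\n— covariate screens: age correlation and p-values per cell —")
print(report["covariates"].round(3).to_string(index=False))

inner = report["covariates"].query("metric == 'diameter' and field == 'inner'")
print(f"\ninner-subfield diameter change vs age: r = {float(inner['age_r'].iloc[0]):.3f} "
      f"(generator truth −0.17; a single n=167 cohort estimates r to about ±0.08)")
# With no treatment effect built in, the adjusted arm differences hover
# around zero and none should fall below the Bonferroni threshold of 0.005;
# the age correlation in the inner-diameter cell recovers the built-in −0.17
# up to sampling noise.
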