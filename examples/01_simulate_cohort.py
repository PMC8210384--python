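"""Simulate a CHARLS-like panel cohort and inspect its structure.

The generator produces a balanced four-wave panel of middle-aged and
elderly respondents: per-stratum demographic margins, log-normal
household income per capita, gamma sampling weights, and a binary
inpatient-utilization outcome drawn from a probit model with a pro-poor
income-rank gradient and wave intercepts that make prevalence rise.
"""

import numpy as np

from equitrend import GeneratorConfig, generate_cohort

cohort = generate_cohort(GeneratorConfig(n_individuals=5000, seed=11))

print(cohort.head(4).T)
print(f"\nrows: {len(cohort)} (5000 persons x 4 waves)")
print("\nweighted utilization rate by wave:")
for wave, g in cohort.groupby("wave"):
    rate = np.average(g.y, weights=g.weight)
    print(f"  {wave}: {100 * rate:5.2f}%")
print("\nThe rate climbs from about 8% to about 19% across waves — the"
      "\nrising-prevalence profile the wave intercepts were chosen for.")
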