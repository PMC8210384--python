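"""Trend layer: rates by wave, chi-square tests and adjusted odds ratios."""

import pandas as pd

from equitrend import (
    GeneratorConfig,
    chi_square_test,
    fit_logistic_or,
    generate_cohort,
    rate_table,
)
from equitrend.pipeline import DEFAULT_DETERMINANTS, _prepare, AnalysisConfig

cohort = generate_cohort(GeneratorConfig(n_individuals=6000, seed=44))
cfg = AnalysisConfig()
df, _ = _prepare(cohort, cfg)

print(rate_table(df, "y", ["stratum", "wave"], "weight").round(4).to_string(index=False))

counts = pd.crosstab(df.wave, df.y)
res = chi_square_test(counts.to_numpy())
print(f"\nchi-square across waves: stat={res.statistic:.1f}, "
      f"df={res.df}, p={res.p_value:.2e}")

X = df[list(DEFAULT_DETERMINANTS)].astype(float)
for wave in ("2013", "2015", "2018"):
    X[f"wave_{wave}"] = (df.wave == wave).astype(float)
ors = fit_logistic_or(X, df.y.to_numpy(), df.weight.to_numpy())
print("\nadjusted odds ratios (wave effects, reference 2011):")
print(ors[ors.variable.str.startswith("wave")].round(2).to_string(index=False))
print("\nRising wave ORs reproduce the generator's increasing intercepts —"
      "\nutilization grows over time after adjusting for the covariates.")
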