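# Methods

## Setting and model

The package measures income-related inequality and inequity in a binary
health outcome — inpatient health service utilization (any hospital stay
in the past year) — across the waves of a weighted panel survey of
middle-aged and elderly respondents, with rural and urban strata
analyzed separately (their health-system environments differ enough that
pooled ranking would conflate between-stratum income differences with
within-stratum inequity; a pooled "total" block is reported as well).

### Fractional ranks

Observations are ordered by household income per capita (sum of income
components divided by household size). With weights normalized to sum
one, observation *i* gets rank `γᵢ = (cumulative weight of everyone
poorer) + wᵢ/2`; tied incomes share the midpoint rank of their combined
weight block. The weighted mean of γ is 0.5 by construction — tested as
an exact identity (1e−12) — and this is what makes the covariance
formulas below well-centred. Ties-to-midpoint is a genuine choice; it
affects indices in roughly the fourth decimal on heavily tied data.

### Concentration index family

The covariance-scale (generalized) index is `GC = 2·cov_w(y, γ)` with a
*population* covariance (weights normalized to one, no n−1 correction —
required for the rank-mean identity to hold exactly). The standard index
is `C = GC/μ`. For a binary outcome both are bounded well inside ±1, so
the Wagstaff normalization `GC/(μ(1−μ)) = C/(1−μ)` (bounds ±1) and the
Erreygers correction `4μC` are provided.

**Reporting convention.** Index tables label the covariance-scale GC as
"CI" and `GC/(μ(1−μ))` as "adjusted CI". This pair is self-consistent:
the adjusted value is the Wagstaff-normalized index whichever scale the
unadjusted column lives on, and the decomposition's HI footer follows
the same convention (covariance scale; its adjusted form divides by
μ(1−μ)). Internally the `DecompositionTable` keeps the standard (÷μ)
scale so that `contribution = elasticity × Cₖ` holds exactly; the
renderer multiplies by μ. The two routes to the adjusted HI —
standard-scale HI ÷(1−μ) and covariance-scale HI ÷ μ(1−μ) — are
algebraically identical, which the pipeline tests assert.

### Confidence limits

The default interval is a Taylor linearization ("delta") of `2A/μ` with
`A = E_w[y(γ−½)]`, treating ranks as fixed: the influence of observation
*i* is `(2/μ)(aᵢ − (A/μ)(yᵢ−μ))` with `aᵢ = yᵢ(γᵢ−½) − A`, and the
variance is `Σ wᵢ² uᵢ²`. This matches the robust standard error of the
convenient regression and ignores the (second-order) sampling
variability of estimated ranks; simulation in the test suite shows
95% intervals covering a known true index at ~95% for n = 20,000.
A seeded nonparametric bootstrap (resampling observations with their
weights, re-ranking each resample) is available and agrees with the
delta intervals within 10% relative width at n = 5,000.

Degenerate inputs are explicit: μ = 0 (or μ ∉ (0,1) where a
normalization needs it) raises an error rather than returning 0; a
constant outcome returns a zero index with zero-width limits and a
`DegenerateDataWarning`.

### Concentration curves

`L(p)` accumulates weighted outcome share against weighted population
share at observation breakpoints; `C = 1 − 2·(trapezoid area)` is exact
(tested to 1e−8). Classification against the diagonal takes a tolerance:
with a binary outcome the empirical curve is locally jagged (a run of
zeros among the poorest pulls `L − p` slightly negative), so the
pipeline classifies at tolerance `n^{-1/2}` — the scale of the curve's
sampling noise — while the function itself defaults to a strict 1e−9
for analytic inputs. A curve on the diagonal is classified "crossing":
no strict side can be claimed.

### Decomposition and horizontal inequity

A weighted probit (pseudo-likelihood via variance weights; HC0 sandwich
covariance; logit available) indirectly standardizes utilization for
need. Marginal effects use the linear-approximation convention — one
common scale factor `E_w[φ(x'β)]` multiplying every coefficient, dummies
treated as continuous — because the decomposition identity requires a
single linear coefficient per variable; evaluate-at-means is available
as a diagnostic flag but not used in contributions. Elasticity
`ηₖ = βᵐₖ x̄ₖ/μ`, determinant index `Cₖ` computed over the *same* ranks
and weights as the outcome index, contribution `ηₖCₖ`. The residual is
the closure term `C − Σ contributions` (absorbing the generalized error
and the linearization error), which makes the decomposition identity and
the need/non-need partition `HI = C − Σ_need` exact by construction —
asserted at 1e−12 on every run.

The default need set is sex, age group, disability and chronic disease;
it is a configurable role map, as is the full determinant list (age and
sleeping-hour dummies, education, insurance, income-group dummies,
living alone, non-smoking, non-alcohol, disability, chronic disease —
reference categories: male, 45–50, ≤elementary, uninsured, low income,
living with others, 7–8 h sleep, smoker, drinker, no disability, no
chronic disease).

### Trend layer

Weighted rates per stratum × wave; Pearson chi-square tests of rate
differences across waves (no continuity correction by default — the
large-sample survey convention; Yates available); pooled person-wave
logistic regression with wave dummies on the baseline covariates,
reported as odds ratios with Wald limits. The logistic fit uses the
survey weights by default (recorded in the run metadata); an unweighted
fit is a parameter away. No multiplicity adjustment is applied; α = 0.05
two-tailed is reported as-is.

## Synthetic cohort generator

The generator emulates the structure of a CHARLS-like panel:

- **Margins.** Time-fixed categorical covariates drawn per stratum to
  first-wave margins (e.g. rural female 0.549, rural insured 0.928,
  rural chronic disease 0.669, urban ≥middle-school education 0.621),
  rural share 0.823. Matched within 3 binomial SE at n = 10,000 in tests.
- **Income.** Log-normal household income per capita (log-location 8.8,
  log-scale 1.0, CNY), household size on {1..6}; income is positive and
  right-skewed, the standard stylization. Weighted tertiles are assigned
  within stratum × wave cells (pooled assignment available through the
  public `assign_income_groups`); boundary ties go to the lower group.
- **Weights.** Gamma with mean 1 and CV 0.5, independent of everything
  else — a neutral stand-in for design weights.
- **Outcome.** Probit `y ~ Bernoulli(Φ(c_wave + x'β))`. Income enters
  through its within-cell fractional rank with coefficient −0.30
  (pro-poor) by default; rank, log-level and group-dummy entry are all
  supported, since how income enters the utilization process is an open
  modelling choice. Wave intercepts (−1.871, −1.609, −1.470, −1.343)
  were calibrated once, by solving `E[Φ(c + x'β)] = target` on a large
  covariate draw, to the rising prevalence profile 8%, 12.5%, 15.5%,
  18.6%.
- **Panel.** Balanced; covariates, income and weights are time-fixed and
  only the outcome is redrawn per wave. Attrition, income dynamics,
  household rosters and the original four-stage sampling design are
  deliberately not modelled — so passing tests demonstrate estimator
  correctness and calibration under clean conditions, not robustness to
  attrition bias, design effects or measurement error in real survey
  data.

Generation is fully deterministic given the config (byte-identical CSV).

## Problem sizes used in validation

Estimator-calibration checks use 200 replicates at n = 20,000 for probit
Wald coverage (pooled over coefficients, required within [93%, 97%]) and
for concentration-index interval coverage against a quadrature truth
(probit-in-rank design, where μ and cov(y, γ) reduce to one-dimensional
integrals); the null-gradient centering check uses 200 replicates at
n = 4,000. Property tests use brute-force definitional oracles at n ≤ 8
(1e−12), a grid-search ML oracle at n = 50 (1e−3), and a hand-rolled
IRLS oracle for the logistic fit (1e−6).

## Known limitations

- The delta-method interval ignores rank-estimation variability; at the
  sample sizes validated this is negligible, but very small samples
  should prefer the bootstrap.
- Percentage contributions are unstable when the total index is near
  zero (they are ratios to it); the total is reported alongside so
  readers can judge.
- Standard errors for individual contributions are not provided;
  uncertainty in HI should be assessed by bootstrapping the pipeline.
- The curve-side classification at tolerance `n^{-1/2}` can read a null
  cohort as one-sided in borderline cases; it is descriptive, not a
  dominance test.
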