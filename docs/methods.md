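# Methods

## Scope and data model

The package implements a two-stage cost-of-illness analysis for myocardial
infarction (MI). Stage one estimates current per-person annual chronic
management costs from an individual-level linked-cohort-style table (one
row per person per follow-up year). Stage two projects the population
cost burden over 20 annual cycles with a dynamic multistate Markov model.
Real inputs of this kind are restricted linked administrative data; the
synthetic-data module generates tables with the same schemas and the
statistical structure the analysis assumes, so the pipeline is fully
testable. All grids use single-year ages 30–99 crossed with sex; costs are
in 2019 AUD and no currency deflation is performed (inputs are assumed
pre-adjusted).

## Chronic cost regression

Annual chronic cost is modelled as gamma-distributed with mean µ linked to
a linear predictor through the inverse link, η = −1/µ (the canonical link
for the gamma family; the sign is a convention absorbed by the
coefficients, and the package verifies that fitted means are identical
under −1/µ and 1/µ). Fits are by IRLS (statsmodels GLM) with person-years
of follow-up as prior weights, convergence tolerance 1e−8 within 100
iterations, dispersion by Pearson χ².

Design choices, each genuinely open in this class of analysis:

* **Zero costs.** A gamma GLM needs positive outcomes. Rows with exactly
  zero cost are shifted by +1 AUD by default (`zero_policy="shift"`;
  `"drop"` available). Negative costs are rejected with row indices.
* **Splines.** Continuous age enters through a natural cubic spline on
  5-year band midpoints, df = 3, knots at person-year-weighted quantiles;
  follow-up year uses df = 2 in the surface model. The natural basis is
  linear beyond its boundary knots, which makes prediction at single-year
  ages 30–99 outside the observed midpoints (32–97) a controlled linear
  extrapolation. The basis is implemented in-package (standard truncated
  power construction) so knots serialize and the training design matrix is
  exactly reproducible.
* **Adjusted estimates are marginal.** For a level v of exposure X, the
  adjusted cost is the person-year-weighted average of predictions with X
  set to v for every row — a population-level per-person cost — rather
  than a prediction at reference covariates. With the canonical link the
  overall marginalized estimate equals the weighted mean observed cost.
* **Confidence intervals.** Delta method on the response scale around the
  marginalized estimate. Coefficient covariance uses the
  heteroscedasticity-robust (HC0 sandwich) estimator by default:
  person-year weights capture exposure, but the variance of a partial
  final year need not scale as 1/weight (it is not an average of
  independent sub-years), and the sandwich form is valid under either
  variance model. Model-based covariance is available
  (`cov_type="nonrobust"`).
* **The cost surface** is fitted per sex with an age-spline ×
  follow-up-spline interaction and evaluated on the full 30–99 × 1..K
  grid. Any non-positive or non-finite cell rejects the surface. The K+
  tunnel in the projection maps to the year-K surface value.

## The dynamic Markov model

States: alive-no-MI; alive-new-MI (exactly one cycle — follow-up year 1);
alive-post-MI with tunnel slots indexed directly by follow-up year 2..K,
the last slot a K+ cap; and three absorbing death states (other-cause,
fatal-MI, post-MI). Each annual cycle applies, in order:

1. **Inflow**: a new cohort of 30-year-olds plus net migrants at every
   age, both split between no-MI and the post-MI K+ cap by MI prevalence
   (prevalent entrants are treated as long-standing disease).
2. **Transitions** at the current age: exits from no-MI use
   `tpsum = 1 − exp(−(λ+µ_other)·ℓ)` split proportionally to the competing
   rates, with the MI share divided into fatal (p_fatal, applied at the
   event) and non-fatal; both MI states carry the annual post-MI death
   probability `1 − exp(−µ_post-MI·ℓ)` (no separate first-year death rate
   beyond p_fatal is specified, and the published state diagram draws
   µ_post-MI from both MI states); survivors advance one tunnel year,
   accumulating in the K+ cap. There is no recurrent-MI transition:
   recurrence costs are inside the chronic cost surface.
3. **Ageing**: everyone ages one year; those passing 99 exit alive
   (tracked separately from deaths).

Rates are held constant over calendar time. Person-years per cycle are
the end-of-cycle census (no half-cycle correction). The recorded census
is taken before ageing, i.e. at the age at which the cycle was lived,
which is also the age used for costing. The per-cycle accounting
identity — alive stock plus cumulative deaths and alive-exits equals the
initial stock plus cumulative inflow — holds to 1e−9 relative and is
asserted in the tests.

**Costing.** Acute: (non-fatal MIs + fatal_acute_fraction × fatal MIs) ×
uniform acute unit cost, with fraction 0.5 in the base case (half of fatal
events assumed to occur in hospital) and 1.0 in a scenario. Chronic:
undiscounted MI person-years × surface cost at (sex, current age,
follow-up year). Discounting multiplies each calendar year's monetary
flow by (1+r)^−(year−2019), so the first projection year is undiscounted,
with r = 0.05 in the base case and 0/0.03 in scenarios. Total = acute +
chronic exactly, cellwise. Fatal MIs receive no chronic cost in their
event year.

**Microsimulation oracle.** An independent stochastic implementation draws
integer transitions from the same probabilities, cell-by-cell multinomials
being distributionally identical to per-individual draws. The initial
population is an exact multinomial allocation of n individuals; entries
and migrants arrive as Poisson counts at the scaled means. Its expectation
equals the deterministic trace, so agreement within sampling error (4
binomial SEs per state-year; 2% on total events and person-years at
n = 2×10⁵) validates the cohort engine's bookkeeping. Cause-specific
event totals are checked through the per-state bound rather than the 2%
band because only ~3k fatal events are sampled at that n (pure sampling
SE ~2%).

## Probabilistic sensitivity analysis

Each uncertain input table gets a (mean, SE) distribution: gamma for
rates, lognormal for unit costs and the cost surface, beta for the fatal
proportion and prevalence, fixed for population counts. Hyperparameters
solve the stated moments exactly. One draw per iteration scales the whole
table — a shared age-profile multiplier that preserves the age gradient —
with beta draws taken on the table's population-weighted mean level,
converted to a multiplier and clipped back to [0,1] cellwise. Default SEs
are ~3–5% of the mean; the exact per-parameter assignments of the source
analysis are not public, so these are declared defaults, not a
transcription. Uncertainty intervals are the 2.5th–97.5th percentiles of
1000 iterations; the point estimate always comes from the deterministic
all-means run and is therefore invariant to the iteration count and seed.
Iteration seeds are spawned from one master seed (common random numbers
across configurations).

## Synthetic data: what it emulates, and what it does not

The cohort generator draws covariates independently from configured
marginals (sex, MI subtype, diabetes, hypertension, IRSD quintile, 5-year
age band), a geometrically-truncated follow-up length (dropout 0.33/year,
max 6 years), and gamma costs (shape 0.7, CV ≈ 1.2) around a
multiplicative mean surface — log-linear in age (+0.9%/year), declining
12%/year of follow-up, with subtype/comorbidity/sex/IRSD multipliers
chosen to mirror a linked Australian MI cohort (~59k people, ~136k
person-years, year-1 cost ≈ AUD 15.9k declining to ≈ 8.5k by year 6,
overall ≈ AUD 14k per person-year). The final follow-up year gets a
uniform (0,1] partial person-year; earlier years are full. A single
dropout process stands in for death and censoring jointly, and no
index-admission episodes, coded diagnoses or item-level claims are
simulated.

The projection input generator produces Gompertz-like age profiles:
incidence 4.0e−4·e^(0.075·(age−30)) for males (55% of that for females),
background mortality 6.0e−4·e^(0.087·(age−30)), post-MI mortality
0.01 + 2.5 × background, fatal proportion rising logistically from 3% to
~50%, MI prevalence rising to 45%/28% (M/F) at the oldest ages, an
initial population of ~14.3M aged 30–99, 320k new 30-year-olds and ~59k
net migrants per cycle, and a AUD 10,000 acute unit cost. These defaults
were calibrated once against the published national figures for Australia
(≈40,200 MI events in 2018, of which ≈6,200 fatal; ≈0.6M prevalent
person-years per year), and the resulting base case lands at AUD ~82B
over 20 years with a ~93% chronic share — the right scale and
composition. Because covariates are independent and rates are smooth
parametric curves, passing tests demonstrate correctness of the
estimation and projection machinery, not the realism of any particular
epidemiological detail: real cohorts have correlated covariates,
non-geometric censoring, calendar trends and cost outliers that the
generator does not reproduce.

## Numerical conventions

Probabilities are computed with `expm1` (accurate for small rates; the
small-rate error |tp − r·ℓ| ≤ (r·ℓ)² is property-tested). Rates must be
nonnegative; a zero rate sum yields zero transition probabilities. All
AUD values are kept at full double precision internally and rounded only
in rendered tables (percent changes to one decimal, headline AUD to 0.1
billion, matching the field's reporting conventions). Problem sizes used
in the checks — 50,000-person cohorts for GLM recovery, 2×10⁵ individuals
for the microsimulation oracle, 1000 PSA iterations — were chosen as the
smallest sizes at which the Monte-Carlo tolerances are meaningful.

## Known limitations

* Acute unit cost uniform by age and sex (as in the base analysis).
* No calendar-time trends in rates; constant-rate projections of this
  kind tend to overestimate burden.
* No productivity, out-of-pocket or informal-care costs.
* The adjusted-estimate marginalization and the PSA distribution
  assignments are declared package conventions where the source analysis
  left them unspecified.
* Surface cells at extrapolated corners (age 30 or 99 at extreme
  follow-up years) carry 3–6% prediction SE at realistic cohort sizes;
  recovery guarantees are therefore stated on exposure-weighted averages,
  not individual corner cells.
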