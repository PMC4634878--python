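# Methods

## Problem and data model

`countyrisk` estimates, for every US county with at least one recorded
police-shooting incident, the probability that a resident of a given
race/ethnicity (black, hispanic, white) and armed status (armed, unarmed)
was shot by police over a multi-year observation window, and the relative
risk ratios between those six cells.  Raw county-level ratios are often
undefined (a county with three unarmed black victims and zero unarmed white
victims has an infinite raw ratio); hierarchical partial pooling
regularizes the denominators away from zero while preserving genuine
heterogeneity across counties.

### Stage 1: hierarchical binomial model

For county *c*, cell *d* (ordering `BU, BA, HU, HA, WU, WA`), with
race-specific census population `N[c, r]` and shooting count `S[c, d]`:

    S[c, d]  ~ Binomial(N[c, r(d)], theta[c, d])
    theta[c] = inv_logit(Theta[c])
    Theta[c] ~ MultivariateNormal(mu, Sigma),  Sigma = Diag(sigma) rho Diag(sigma)

Priors: `mu_d ~ Normal(-14, 4)` (the 4 is a standard deviation; on the
probability scale the central mass spans roughly 1e-9 to 1e-3 per window,
which brackets any plausible shooting rate), `sigma_d ~ HalfCauchy(0, 5)`,
and a uniform prior over valid 6x6 correlation matrices (LKJ with shape 1).

Relative risks are computed per posterior draw, e.g.
`R[c] = theta[c, BU] / theta[c, WU]`, so all posterior dependence between
numerator and denominator propagates into the ratio summaries (posterior
median and the equal-tailed 2.5%/97.5% interval, computed with
linear-interpolation percentiles so results are bit-stable at fixed draws).

Two pooled (nation-wide) summaries are available and always labelled in the
output: `hyper_mean` (ratio of `inv_logit(mu)` components per draw — the
risk ratio of the population-level average county; the default) and
`median_of_counties` (per-draw median across counties of the county
ratio).  They answer slightly different questions and are both exposed
because published pooled figures of this kind rarely state which
convention they use.

### Stage 2: measurement-error ecological regression

County log risk ratios enter the second stage only through their
first-stage posterior mean `mu_R[c]` and standard deviation `sigma_R[c]`
(floored at 1e-6).  The structural model is

    Y[c] ~ Normal(mu_R[c], sigma_R[c])      (measurement)
    Y[c] ~ Normal(X[c] beta, sigma)         (regression)

with `beta_j ~ Cauchy(0, 5)` and `sigma ~ Exponential(1)`.  Since both
statements are Gaussian in `Y[c]`, the latent outcome marginalizes out
exactly: `mu_R[c] ~ Normal(X[c] beta, sqrt(sigma^2 + sigma_R[c]^2))`.  The
sampler targets this marginal posterior (fewer dimensions, no funnel
geometry) and reconstructs `Y[c]` per posterior draw from its conjugate
normal conditional; the joint posterior over `(beta, sigma, Y)` is
mathematically identical to sampling the latent variable directly.

Covariates — total population, percent black, median income, Gini index,
a Google-search-based racism proxy, and race-specific assault and weapons
arrest rates — enter as natural logarithms, uncentered, matching the
published regression equation.  An optional `center=True` flag centers the
predictors for sampler stability and back-transforms the intercept per
draw for reporting; with diffuse coefficient priors the practical
difference is negligible, but the default stays on the natural scale so
the prior is applied exactly as written.

Twenty-five candidate models `M1..M25` are fit side by side, from
intercept-only up to all nine predictors; race-specific crime rates always
enter as white/black pairs.  Coefficients are annotated with star codes
derived from the posterior mass opposing the sign of the posterior mean
(`*` for 0.05 < p <= 0.10, `**` for 0.01 < p <= 0.05, `***` for
p <= 0.01).

**Missing covariates.** Entries that are absent — and zero arrest rates,
whose logarithm is undefined — become latent parameters with a
`Normal(mean, sd)` prior matched to the observed entries' log-scale
moments, sampled jointly with the coefficients (Bayesian imputation).  A
covariate with no observed entries at all is an error.

**Robustness re-parameterization.** A `sum_diff` option replaces each
white/black crime pair with the pair's sum and black-minus-white
difference.  The sum is logged like every other rate; the difference can
be negative, so it enters on the natural scale.  This lets the regression
ask "does overall crime predict bias?" and "does the racial crime gap
predict bias?" directly.

**Percent-black definitions.** Published county tables sometimes describe
this covariate as a percentage and sometimes as a black-to-white
population ratio.  The covariate table is taken at face value (`pct_black`
column); because the covariate enters in logs, the two definitions differ
only through `log(pct_white)`, and either can be supplied in the input
table.  Arrest rates are per 10,000 residents with total-population
denominators in the synthetic generator; real covariate tables are
consumed as given.

## Sampler

No gradient-based MCMC library ships with the package's environment, so
`countyrisk.sampler` implements the No-U-Turn sampler natively: multinomial
state selection along doubled trajectories, a divergence threshold of 1000
on the energy error, dual averaging of the step size toward a target
acceptance statistic (0.85 stage 1, 0.9 stage 2), and Stan-style expanding
warmup windows for a diagonal mass matrix.  All model gradients are
analytic; the correlation matrix is parameterized by canonical partial
correlations (tanh-transformed, with the exact log-Jacobian) and the
county effects are non-centered (`Theta[c] = mu + L z[c]`), which is the
geometry the Cholesky-factor formulation of the model implies and which
keeps sampling efficient when counts are sparse.

Gradient correctness is enforced in the test suite by finite-difference
comparison on every log density, and sampler correctness by exact oracle
checks: a fixed-hyperparameter single-county posterior against 1-D grid
integration (tolerance 0.02 on the median and both interval endpoints),
and the no-measurement-error regression against 2-D/3-D grid integration
(tolerance 0.05 on posterior means).  Convergence is monitored with split
R-hat and bulk ESS (via arviz) over the hyper-parameters and all county
probabilities; exceeding the configured R-hat threshold raises a
diagnostic-carrying error rather than returning silently bad draws.
Defaults are 4 chains, 1000 warmup and 1000 kept iterations, R-hat
threshold 1.01, and a mandatory seed; fits are bit-reproducible for a
fixed seed and configuration.

## Record handling

Incident records are kept only when (1) armed status is clearly armed or
unarmed, (2) race/ethnicity is clearly black, hispanic, or white, (3) the
year is 2011-2014, and (4) a county can be assigned.  Unparseable fields
degrade to UNKNOWN/missing at read time and are dropped (and counted,
per rule) only at the cleaning step, so nothing is silently lost.
Duplicate listings of the same victim are removed by two rules: exact
normalized-name matches sharing (year, county), and names within edit
distance 2 that agree exactly on (year, age, race, county) — the
operationalization of "spelling variations of the same victim".  The
deduplication keeps first occurrences and is idempotent.  Race categories
other than black/hispanic/white are excluded because the model estimates
six probabilities per county; armed status is never imputed.

Counties are keyed by zero-padded 5-character FIPS strings throughout;
county names are never join keys.  Aggregation conserves records exactly
(checked by round-trip tests) and refuses cell counts exceeding their
census denominators.

## Synthetic-data generator

The generator runs both model stages generatively so the whole pipeline is
testable offline.  Defaults: 100 counties, race populations log-uniform
between 1e3 and 1e6, logit-scale means near -11 — per-window probabilities
in the 1e-6..1e-4 band, the sparsity regime where partial pooling matters —
with county scatter 0.5 and a mild uniform positive correlation (0.3)
between cells.  The built-in means encode armed-vs-unarmed ratios near 3
and a black/white unarmed ratio near e^1.2 ~ 3.3, in the spirit of the
published estimates.  Counties whose simulated counts are all zero are
dropped (the model's inclusion rule) and recorded in the truth object
rather than resampled; at default scale roughly 5-10% of counties drop.
Incident records are materialized one per count unit with synthetic names,
years, and ages, and noise records (misspelled duplicates, out-of-window
years, unknown races) can be injected at configured rates as *extra* rows
so cleaning can be checked against exact injected totals.

Stage-2 covariates are drawn from log-normal-style marginals with
realistic locations (county population ~1e5, median income ~$45k, Gini
0.35-0.55, arrest rates tens per 10,000) and the true log risk ratio is a
linear function of the logged covariates plus Gaussian noise, enabling
coefficient recovery with known truth and masking experiments for the
imputation path.

What the generator does *not* emulate: spatial correlation between
counties, the construction of the racism-proxy index, reporting biases in
crime covariates, and incomplete incident capture.  Passing tests
therefore demonstrate that the estimators recover the generative process
they assume — not that real police-shooting data satisfy that process.

## Calibration checks and their scale

The acceptance layer runs, at sizes chosen to keep a desk run short:

- oracle equivalence on a single fixed-hyper county (2 chains, 2000 kept
  draws);
- stage-1 recovery over 20 replicates of 50 counties with 1e5 residents
  per race (2 chains, 300+300 iterations each): per-component 95%
  intervals must cover the true `mu` in at least 17/20 replicates, and the
  replicate-averaged (geometric mean) pooled risk-ratio median must land
  within 15% of the true population-level ratio — a single replicate's
  median has sampling spread near 30% at this data sparsity, so the bound
  binds on the average, not each replicate;
- stage-2 recovery at 200 counties (coefficients within two posterior
  standard deviations) plus the grid-oracle limit;
- exact record round trips and noise accounting;
- the golden 25-model covariate pattern and star-code band boundaries.

## Numerical choices

- Binomial likelihoods are evaluated on the log scale with `logaddexp`;
  probabilities are never clipped.
- Cells with zero census population and zero shootings contribute nothing;
  a shooting in a zero-population cell is a hard data error.
- `sigma_R` is floored at 1e-6 to avoid degenerate zero-noise likelihoods.
- Saturated correlation transforms (tanh at +-1, exhausted row norm) return
  a -inf log density and are rejected by the sampler as divergences rather
  than propagating NaNs.
- Percentiles use linear interpolation between order statistics; ratio
  reciprocity (swap-and-invert of numerator and denominator) is exact
  whenever the percentile positions land on order statistics.

## Known limitations

- Absolute risks are out of scope: with incomplete incident capture only
  relative risks are identified.
- No spatial (CAR/ICAR) structure between counties; no department- or
  state-level nesting.
- The ecological regression inherits the ecological-inference caveat:
  county-level associations need not hold at the individual level.
- The NUTS implementation uses a single fixed divergence threshold and
  diagonal mass matrix; strongly correlated posteriors (e.g. uncentered
  regressions with large-magnitude covariates) mix more slowly than they
  would with a dense mass matrix — the `center` flag exists for that case.
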