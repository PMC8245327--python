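# Methods

`saeratio` quantifies how representative a set of clinical trials is of
the population treated in routine care, using serious adverse events
(SAEs) as the yardstick. Trials must record and report all SAEs —
events that are life-threatening, fatal, or cause/prolong
hospitalisation — irrespective of suspected cause, and most SAEs are
hospitalisations or deaths. If a trial population resembled the treated
community population, its SAE rate should resemble the community's
all-cause emergency hospitalisation/death rate at the same ages and sex
mix. The package measures the gap.

## The estimands

Three quantities are estimated from a trial registry (aggregate data
only) and an individual-level community cohort:

1. **Incidence rate ratio (IRR)** between older-people trials (minimum
   inclusion age ≥ 60 years) and standard trials:
   y_i ~ Poisson(μ_i), log μ_i = log T_i + α + β·older_i (+ covariates)
   + u_i, u_i ~ Normal(0, τ²), where T_i is the trial's estimated
   person-time and u_i a trial-level random intercept. IRR = exp(β).
2. **Standardised ratio (SR)** of community-expected to trial-observed
   events, per group: the same model with offset log E_i, the expected
   count from indirect standardisation. The likelihood estimates
   observed/expected; every reported SR is the inverse, exp(−α), so
   SR > 1 means community rates exceed trial SAE rates. The **ratio of
   SRs** (older vs standard) is exp(−β).
3. **Arm IRR** (treatment vs placebo) in placebo-controlled trials,
   with the trial as the random-intercept grouping unit shared by its
   two arms — a check that SAE rates are treatment-agnostic enough to
   pool arms.

### Person-time

Trials report counts, not person-time. Exposure is estimated as
follow-up × (participants − 0.5 × SAE count): a participant with an SAE
is assumed to contribute on average half the follow-up window. Years
are 365.25 days throughout.

### Expected counts (indirect standardisation)

The community cohort provides a Poisson log-linear rate model for
emergency hospitalisations/deaths per person-year — by default
intercept + age (linear, years) + sex indicator, with log person-years
as exposure offset (quadratic-age and 5-year-band variants are
config options; the export contract — coefficients plus
variance-covariance matrix — is identical for all). Ages are centered
at 60 during fitting and un-centered on export, so serialised models
are on the natural scale.

Each trial's age distribution is reconstructed as a normal distribution
truncated to its eligibility window and calibrated to its reported
moments:

* mean and SD reported — both moment equations are solved for the
  underlying (μ, σ);
* mean only — σ is fixed at `default_sd` (8 years) and μ solves the
  mean equation. The 8-year default reflects typical adult
  hypertension-trial age SDs; it is a configurable assumption, not an
  estimate, and a sensitivity flag allows reruns at other values.

The solved distribution is discretised into 1-year age bins on a
support clipped to [18, 100] years (adult trials, finite quadrature),
each bin split between sexes by the reported % women. The expected
count is person-time × Σ_strata weight × modelled rate, i.e. person-
time is split across strata in proportion to the weights (exchangeable
follow-up). Results are insensitive to the bin width (halving it moves
expected counts by < 0.1%).

Feasibility: a reported SD cannot exceed the uniform limit
width/√12 on a finite window, nor the exponential limit |mean − bound|
under one-sided truncation; infeasible targets raise an error naming
the bound. The solver uses a fast 2-D root find with a nested
monotone-bracketing fallback (the truncated mean is increasing in μ;
given a mean-matched μ, the truncated SD is increasing in σ), verified
against direct quadrature of the truncated density to 1e-8.

### Per-trial expected/observed ratios

Uncertainty in the ratio combines two sources, mirrored by two Monte
Carlo streams of `n_samples` (default 10 000) draws:

* coefficient uncertainty — draws from MVN(coefficients, vcov) of the
  rate model, each mapped to an expected count through the trial's
  age-sex distribution;
* count uncertainty — draws from a Poisson at the observed count,
  **zero-truncated**: an untruncated denominator makes the ratio's mean
  infinite, and trials with zero observed events are excluded outright
  (their ratio would be infinite). The truncation is recorded in the
  output metadata.

The streams are paired elementwise and summarised by the mean and
2.5th/97.5th centiles. A full cross-product pairing is available behind
a flag (capped at 2×10⁷ ratios). Observed counts pool clinical-endpoint
events with SAEs for hard-outcome trials, since both represent
hospitalisations or deaths; this pooling is applied before all ratio
and SR computations (the IRR models use SAE counts alone). Trials with
one observed event are flagged `unstable_low_events` (their ratios are
extreme); trials lacking mean age or % women are excluded from
standardisation with a logged reason.

## Posterior computation

The hierarchical Poisson models are fitted by integrating the random
intercepts out of the likelihood with adaptive Gauss-Hermite quadrature
(20 nodes, re-centered at each group's conditional mode and scaled by
the conditional curvature — the integrand is log-concave, so a short
Newton iteration finds the mode) and sampling the remaining
fixed-effect + τ vector with random-walk Metropolis: a Laplace
proposal covariance, Robbins-Monro scale adaptation during warm-up, and
chains vectorised so one likelihood evaluation serves all chains. τ is
parameterised as |s| with s unconstrained, turning a Normal prior on s
into a half-Normal on τ without a boundary.

* Priors: Normal(0, 5) on the intercept, Normal(0, 2.5) on other fixed
  effects, half-Normal(0, 1) on τ. A flat-prior/fixed-τ mode exists for
  oracle comparisons (with τ = 0 and flat priors the posterior medians
  match classical Poisson GLM MLEs within 2%, and the single-group SR
  equals the closed-form Σ expected / Σ observed).
* Sampler defaults: 4 chains × 2000 iterations, first half warm-up;
  all configurable.
* Diagnostics: rank-normalised R-hat and effective sample size per
  parameter (arviz); a fit with max R-hat above the threshold (default
  1.01) is flagged, never silently returned. At strongly reduced
  settings the flag trips while summaries remain usable.
* Point summary: posterior median; intervals are 2.5/97.5 centiles.
  Exponentiated-scale centiles are the exponential of the log-scale
  centiles (centile equivariance); the exponentiated mean is computed
  on the exponentiated draws.
* Group SRs are conditional (random intercept = 0) and, in adjusted
  models, evaluated at reference covariate levels (standard group,
  non-renin-inhibitor, placebo comparison, phase 3, soft outcome).

## Sensitivity analyses

1. **Leave-one-out** — refit excluding each trial in turn; a variant
   that fails (e.g. loses a covariate level) is recorded without
   affecting the others. The pipeline caps the number of refits
   (`loo_max_trials`, default 30); calling the module directly refits
   every variant.
2. **Cohort restriction** — drop community participants flagged with
   diabetes, heart failure or chronic kidney disease (possible
   non-hypertension indications), refit the rate model, recompute all
   trial comparisons. Recent myocardial infarction/stroke is a baseline
   cohort-construction exclusion, not a sensitivity variant.
3. **90-day first-event follow-up** — censor each community participant
   at the first event, day 90, or their original end of follow-up,
   whichever is first (matching the short follow-up of most trials),
   refit the rates and recompute; the trial data are unchanged. Under a
   constant hazard this leaves the rate-model intercept unchanged up to
   sampling error, which the tests verify.

## The synthetic study conditions

The generators stand in for the two external data sources and define
known ground truth for every downstream estimator.

**Cohort** (defaults): 56 036 persons; ages truncated-normal with mean
60.6, SD 13.9 on [18, 100]; 50.3% women; up to 3 years of follow-up
censored by an exponential deregistration process at 3%/year; event
counts Poisson under log-rate β₀ + β_age·age + β_sex·I[female]; event
times uniform over follow-up (homogeneous Poisson process), which is
what makes the first-event analysis well-posed. Four comorbidity flags
(recent MI/stroke, diabetes, heart failure, CKD) with configurable
prevalence and rate multipliers feed the exclusion analyses. The rate
coefficients are calibrated from the registry-side anchors — trial SAE
rates near 0.11 (standard) and 0.18 (older) events/person-year at mean
ages 55.6 and 73.1 with community rates 4.2-4.8× higher — giving
β_age = 0.036 per year and β₀ = −2.75 (about 0.46 events/person-year at
age 55.6, male). The generative age-sex rate shape is an assumption;
only its printed consequences are anchored.

**Registry** (defaults): 99 standard + 11 older-people trials; true SRs
4.23 and 4.76; trial-level lognormal heterogeneity SD 0.5; sizes
100-3000 (log-uniform follow-up 28-365 days); mean ages drawn around
55.6 (standard) and 73.1 (older); older trials have minimum inclusion
age ≥ 60; covariate frequencies follow the registry mix (30% renin
inhibitor, ~20% placebo comparison, 35% phase 4, 5% hard outcome); 70%
of trials report an age SD (drawn feasibly for the eligibility window).
Each trial's SAE count is Poisson(E/SR × e^u). Generative means are
**attrition-consistent**: since the estimator uses person-time
follow-up × (n − 0.5·SAE), counts are drawn with mean
λ = m/(1 + 0.5·m/n) (m the full-exposure mean), so the generator's SR
is exactly the estimator's estimand rather than biased by ~0.5·m/n.
Arm-level tables for placebo trials share the trial random intercept
and set the treatment:control rate ratio to 0.81 by default.

**What the generators do not emulate**: death as a censoring event
(deregistration is the only censoring mechanism, so synthetic cohorts
accumulate more person-time and events than a mortality-censored
cohort would); record-linkage structure, coding, or prescriptions;
within-trial arm-level age differences; per-drug pharmacology;
dependence of trial covariates on trial risk (covariates are drawn
independently, so adjusted and unadjusted contrasts coincide in
expectation). Passing recovery tests therefore shows the estimators are
correct under these conditions, not that real registries satisfy them.

**Replicate designs for recovery experiments.** IRR recovery uses the
direct rate-ratio generator (60 standard + 12 older trials, true IRR
1.75); SR recovery uses a balanced 30 + 30 registry at true SR 4.0 in
both groups, so both group SRs carry comparable information at the
tolerance being tested. Both run at heterogeneity SD 0.3: at the
registry default of 0.5 with only ~12 older trials, the information
bound τ/√n ≈ 0.15 on the log scale makes a ±20-25% point-recovery band
narrower than one standard error of any correct estimator, so recovery
at that noise level is not a meaningful test of the code. Coverage
checks (95% intervals covering truth in ≥ 85-90% of 50 replicates) use
reduced sampler settings (2 chains × 1000-1200 iterations).

## Reproducibility

Every stochastic component takes a seed. Pipeline runs derive per-stage
sub-seeds from one global seed via `SeedSequence(seed, spawn_key)`, so
stages can be rerun independently; the emitted manifest (config, hash,
stage seeds, exclusions) reproduces a run's result files byte-for-byte.
Counts serialise as integers, rates and ratios as 6-significant-digit
decimal text.

## Known limitations

* Overdispersion beyond the lognormal trial intercept (e.g.
  negative-binomial within-trial counts) is out of scope.
* The exact covariate form of the community rate model and the per-trial
  age SDs of the original analyses are unavailable; the defaults here
  are declared assumptions with config escape hatches.
* Whether the original 10 000 × 10 000 division was paired or a cross
  product is ambiguous; paired is the default, cross is implemented for
  comparison.
* The random-walk sampler is adequate for these low-dimensional
  marginal posteriors but would not scale to models with many fixed
  effects.
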