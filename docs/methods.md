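# Methods

## Model

Each quality indicator is a binary resident-level outcome y_ij (resident i,
facility j) analysed with a random-intercept logistic model

    logit P(y_ij = 1 | b_j) = x_ij' β + b_j,    b_j ~ N(0, V_G).

The facility intercept b_j carries all modelled between-provider
heterogeneity; x_ij holds the case-mix adjusters. The model assumes a single
level of clustering (residents in facilities), logit link, normally
distributed facility effects, and adjusters acting identically across
facilities. On the latent-response scale the within-facility variance of a
logistic model is fixed at π²/3 ≈ 3.2899, which is what makes the
variance-partition coefficient ICC1 = V_G/(V_G + π²/3) well defined for a
binary outcome.

Covariate coding: age in decades centred at 85 years; care level (1–12) and
CPS (0–6) as numeric scores; depression as the indicator DRS ≥ 3 (the
instrument's clinical threshold); sex as a female indicator. The canonical
adjuster sets are CPS + care level for all indicators, plus age for
polypharmacy and depression + sex for the two pain indicators; they can be
overridden per model.

## Indicator construction

Each indicator applies, in order: (1) listwise deletion of residents with a
missing required item; (2) the indicator's exclusion rule (invalid pain
self-reports; consented restraint use by residents capable of judgment; life
expectancy under six months or assessment-at-admission for weight loss);
(3) the numerator predicate on the remaining eligible residents. Two literal
readings are built in as defaults: a restraint context of "not yet
clarified" stays in the denominator (only an affirmative consent excludes),
and a life-expectancy value of "not collected" does not exclude (only an
affirmative under-six-months judgment does). Pain intensity is ordered
none < mild < moderate < strong < very strong/unbearable, and "moderate or
higher" means the top three levels. The headline prevalence is the mean of
facility rates with its SD; the resident-pooled rate is reported alongside
because the two differ under unbalanced facility sizes.

## Estimation

The marginal likelihood integrates each facility's contribution over b_j by
**adaptive Gauss–Hermite quadrature**: per facility the integrand is
recentred at its posterior mode (found by a damped 1-D Newton iteration,
gradient tolerance 1e-10) and scaled by the curvature there, then evaluated
at the transformed Hermite nodes (order 15 by default; orders 15 and 31
agree to < 1e-6 on the test fixtures, and the quadrature path is verified
against a dense ±8 SD trapezoid integration to 1e-6). The outer
maximization is L-BFGS-B over (β, sd) with sd = √V_G bounded at zero —
parameterizing the SD rather than log-variance keeps the V_G = 0 boundary
reachable, where the likelihood collapses to ordinary logistic regression.
Convergence: projected-gradient tolerance 1e-6, function tolerance 1e-12,
at most 200 iterations, with a short derivative-free polish if the line
search stalls; non-convergence is flagged on the returned fit, never
silent. Duplicate (facility, covariate-pattern, outcome) rows are collapsed
into frequency weights before optimization — an exact transformation of the
likelihood that makes intercept-only designs (two weighted rows per
facility) and discrete-covariate designs much faster.

**Empirical-Bayes effects** are the per-facility posterior modes of b_j at
the ML estimates, with the conditional SD taken from the curvature at the
mode; 95% intervals are estimate ± 1.96 × SD. This conditional-normal
construction (rather than a simulation-based posterior) is the package's
choice; it is standard for single random intercepts and is what the
caterpillar display consumes. A facility whose observed events match its
case-mix prediction has an EB effect near zero, and all effects shrink to
zero as V_G → 0.

**Fixed-effects model.** Rankability needs per-facility effect SEs from a
model with facility indicators instead of a random intercept. Facility
effects use sum-to-zero contrasts (so effects are deviations from the mean
facility, directly comparable to the EB effects) plus the same adjusters;
the fit is plain ML logistic regression (statsmodels). Facilities with zero
or all events have no finite ML effect: they are dropped from the fit,
returned flagged as non-estimable with NaN effect/SE, counted in the
report, and excluded from median(s²) — the median makes rankability robust
to their absence.

## Metrics

* ICC1 = V_G/(V_G + π²/3); values above 0.05 are flagged as relevant
  between-provider variability.
* ICC2 = V_G/(V_G + (π²/3)/k) with k the number of facilities in the fitted
  data — the Spearman–Brown step-up of ICC1 with factor k, i.e. the
  reliability of the facility-level mean.
* Rankability ρ = V_G/(V_G + median(s²)) over the finite fixed-model SEs,
  classed low (< 0.50), moderate (0.50–0.75), high (> 0.75). The
  risk-adjusted fixed-effects model supplies s by default; an unadjusted
  variant is available by overriding the adjuster set to ().
* ICC confidence intervals: parametric bootstrap (redraw b_j from
  N(0, V̂_G), redraw outcomes from the fitted conditional probabilities,
  refit warm-started at the MLE, percentile 2.5/97.5), default 1000
  replicates, seeded and reproducible; a refit-failure rate above 20%
  aborts with diagnostics rather than returning a quietly biased interval.

## Synthetic data

The generator's defaults are the study conditions the package targets: 152
facilities × 75 long-term residents; age truncated-normal (mean 86.1,
SD 8.36, range 65–110); 72.8% female; care level 1–12 with median near 6;
CPS mildly right-skewed; DRS with geometric-type decay putting roughly a
third of residents at the ≥ 3 depression cut; invalid self-reported-pain
answers injected at 13.4% (observed pain 0.7%, bedrails 1.6%, weight loss
0.1% missing).

Two generators are deliberately separate. The **outcome-level** generator
draws y directly from the random-intercept logit model — the exact form the
estimator assumes — so parameter-recovery and calibration results are
interpretable. The **item-level** generator draws the raw item schema; each
indicator gets a latent facility SD whose implied ICC1 matches the
risk-adjusted values observed nationally (0.068 polypharmacy … 0.396 trunk
restraint) and a target prevalence (43.0%, 19.7%, 14.9%, 3.4%, 13.0%, 7.9%).
The intercept that hits each target under the configured facility variance
and case-mix effects is solved at generation time by quadrature + bisection,
so configured prevalences are matched in population average rather than by
hand-tuning.

Item-level joint distributions are not observable from published summaries,
so they are package assumptions, fixed once: the pain-positive mass splits
55/25/10 across daily moderate/strong/very-strong plus 10 nondaily
very-strong; restraint users are 80% "incapable of judgment" and 20% "not
yet clarified", with consented (excluded) users at 1% (trunk) and 3%
(bedrails) of residents; weight-loss events split 45/35/20 between the
30-day criterion only, the 180-day criterion only, and both; 3% of
residents carry a life-expectancy-under-6-months judgment, 5% "not
collected", and 5% are admission assessments. Randomness uses one root seed
with named per-stream substreams (sizes, covariates, facility effects per
indicator, item noise, missingness), so identical configurations are
byte-identical and adding a stream never shifts existing draws.

What the generator does **not** emulate: longitudinal repeated assessments,
instrument-specific export formats, correlated missingness (missingness is
injected completely at random at the configured rates, whereas real invalid
pain self-reports concentrate in cognitively impaired residents),
cross-indicator correlation within resident beyond shared case-mix, and
facility-size correlation with quality. Passing tests therefore establish
that the estimators recover known truth under the assumed model, not that
the model is correct for any particular real population.

## Test problem sizes

Parameter recovery runs 20 replicates of the 152 × 75 design at true ICC1 ∈
{0.05, 0.15, 0.40} (tolerance ±0.03 on the mean estimate). Bootstrap
coverage uses 100 replicates of a 40-facility × 25-resident intercept-only
design at true ICC1 = 0.2 with 200 bootstrap draws each, asserting coverage
in [0.88, 0.99]; the smaller design keeps the ~20,000 model fits tractable
while still exercising the boundary-adjacent behaviour of V̂_G. Null
calibration of the caterpillar flags uses one seeded 152 × 75 draw with
V_G = 0 (≤ 7% of facilities may be flagged). The quadrature oracle fixture
is 5 facilities × 20 residents.

## Known limitations

* A single random intercept only: no crossed/nested levels, random slopes,
  or non-logit links.
* EB intervals are conditional-normal and ignore uncertainty in (β, V_G);
  caterpillar significance flags carry no multiplicity correction by
  default (a Bonferroni option exists) — both choices mirror common
  profiling practice and both are anti-conservative.
* The parametric bootstrap conditions on the fitted model form; it does not
  protect against misspecified random-effect distributions.
* Rankability inherits the instability of fixed-model SEs for rare outcomes
  in small facilities; the median and the non-estimable-facility policy
  mitigate but do not remove this.
* ICC2 grows mechanically with k and is insensitive near 1; rankability is
  the more discriminating summary when ICC1 is small.
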