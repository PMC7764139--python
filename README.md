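# nhqi — nursing-home quality-indicator profiling

`nhqi` asks whether facility-level quality indicators in long-term care —
the percentage of residents with polypharmacy, self-reported or observed
pain, trunk-fixation or bedrail restraints, and weight loss — can tell
nursing homes apart, and how reliably. It is written for biostatisticians
and health-services researchers who need to evaluate indicator sets for
benchmarking or public reporting, and for anyone building simulation studies
of provider profiling with binary outcomes.

The package implements the full chain:

1. **Indicator construction** from resident-level items (medication counts,
   pain frequency × intensity, restraint use and consent context,
   weight-loss flags), with each indicator's stated exclusion criteria and
   listwise deletion of missing items.
2. **Risk-adjusted random-intercept logistic models.** For resident *i* in
   facility *j*,

   ```
   logit P(y_ij = 1 | b_j) = x_ij' β + b_j,      b_j ~ N(0, V_G),
   ```

   fitted by maximum likelihood with adaptive Gauss–Hermite quadrature.
   Case-mix adjusters per indicator: cognitive performance (CPS) and care
   level for all six, plus age for polypharmacy and depression (DRS ≥ 3) and
   sex for the two pain indicators.
3. **Variability and reliability metrics.** On the latent scale the residual
   variance of a logit model is π²/3, so

   ```
   ICC1 = V_G / (V_G + π²/3)                 between-provider variability
   ICC2 = V_G / (V_G + (π²/3)/k)             reliability of the k-facility mean
   ρ    = V_G / (V_G + median(s²))           rankability
   ```

   where the s are facility-effect standard errors from a parallel
   fixed-effects logistic model with sum-to-zero facility contrasts.
   ρ is classed low (< 0.50), moderate (0.50–0.75) or high (> 0.75);
   ICC1 > 0.05 marks relevant between-provider variability. Confidence
   intervals for the ICCs come from a parametric bootstrap.
4. **Empirical-Bayes caterpillar profiles** — shrunken facility effects with
   95% intervals, sorted and flagged against the grand mean — plus a
   synthetic-data generator with known latent facility variance, so every
   stage is testable without access to confidential resident records.

## Worked example

Simulate a national-scale population (152 facilities × 75 residents, the
package's default conditions) and profile all six indicators:

```
$ nhqi simulate --seed 1 --out residents.csv
wrote 11400 residents in 152 facilities to residents.csv

$ nhqi assess --records residents.csv --out-dir assess --seed 1
polypharmacy: ICC1=0.084 ICC2=0.933 rho=0.843 (high)
pain_self: ICC1=0.115 ICC2=0.952 rho=0.792 (high)
pain_observed: ICC1=0.187 ICC2=0.972 rho=0.866 (high)
restraint_trunk: ICC1=0.427 ICC2=0.991 rho=0.827 (high)
restraint_bedrails: ICC1=0.367 ICC2=0.989 rho=0.921 (high)
weight_loss: ICC1=0.132 ICC2=0.958 rho=0.652 (moderate)
```

Reading the first line: 8.4% of the latent variation in polypharmacy sits
between facilities (ICC1 = 0.084, above the 0.05 relevance bar); averaging
over 152 facilities the facility mean is highly reliable (ICC2 = 0.933); and
84% of the observed between-facility spread reflects true differences rather
than sampling noise (ρ = 0.843, "high"). The restraint indicators carry the
most facility-level signal — their generator defaults put roughly 40% of
latent variance at the facility level — while weight loss ranks facilities
only moderately well at 75 residents per home.

`assess` also writes `report.json`/`report.csv` (one row per indicator),
per-facility rate and caterpillar tables, and an exclusion audit;
`nhqi plot` renders the caterpillar panels; `nhqi pipeline` chains
everything from a YAML config. The same operations are importable from
Python (`nhqi.simulate_items`, `nhqi.extract_indicator`,
`nhqi.fit_random_intercept_logistic`, `nhqi.run_pipeline`, ...).

## Layout

```
src/nhqi/simulate.py     synthetic populations (outcome- and item-level)
src/nhqi/indicators.py   indicator definitions, exclusions, facility rates
src/nhqi/glmm.py         adaptive-quadrature GLMM, EB effects, fixed-effects model
src/nhqi/metrics.py      ICC1/ICC2, rankability, parametric bootstrap
src/nhqi/reporting.py    caterpillar data, pipeline driver
src/nhqi/plots.py        caterpillar rendering
src/nhqi/cli.py          nhqi simulate|indicators|assess|plot|pipeline
docs/methods.md          model details, generator assumptions, limitations
```
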