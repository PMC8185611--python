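# Methods

## Scope and model

`trialcea` implements a trial-based economic evaluation comparing a guided
iCBT-I intervention plus usual care against a wait-list control with usual
care, over a 6-month horizon with assessments at baseline, 8 weeks, and 6
months (times 0, 8/52 and 0.5 years). Costs and effects are not discounted at
this horizon. Two perspectives are supported: *societal* (direct medical +
patient/family + productivity costs) and *public health care* (direct medical
costs only), and two effect measures: symptom-free status (Insomnia Severity
Index < 8, strict) and QALYs (trapezoid AUC of linearly interpolated SF-6D
utilities). SF-6D utilities are pipeline inputs; no tariff algorithm is
implemented.

## Costing

Resource use is recorded per recall window (default two 3-month windows) and
valued with a unit-cost table of 2013 German guideline prices (already
indexed by the consumer-price-index factor 1.04). Amounts convert to GBP at
purchasing power parity (€1 = £0.85). Category structure:

| block | categories | valuation |
|---|---|---|
| direct medical | intervention (fixed €299), GP/somatic care, mental health care (sessions + inpatient days by hospital type), medication, allied health | units × unit price; medication as defined daily doses × insurance-weighted price (statutory share 0.89) |
| patient & family | informal care, domestic help, out-of-pocket, travel | informal care at the opportunity-cost rate €23.10/h, domestic help at the replacement rate €18.33/h, travel €0.30/km, out-of-pocket passed through |
| productivity | absenteeism, presenteeism | human capital approach (gross daily wage); Osterhaus (impaired days × inefficiency fraction × wage) or HLQ (recoverable hours × hourly wage) |

Design choices where the source material left room:

* **Rate assignment.** Both hourly rates are published without an explicit
  per-category assignment; informal care uses the opportunity-cost rate and
  domestic help the replacement rate, and both assignments are configurable.
* **Allied-health price.** No unit price is published for allied-health
  contacts (only arm-level cost means); a configurable default of €30.00 per
  contact is assumed.
* **Medication prices.** The drug-registry lookup is out of scope; a
  configurable synthetic table of per-DDD prices with (statutory, private)
  pairs stands in. Weighted price = 0.89 × statutory + 0.11 × private.
* **Inefficiency score.** Stored as a fraction in [0, 1]; questionnaire
  scales map at ingestion, keeping the Osterhaus product dimensionally
  transparent.
* **Rounding.** Internal arithmetic at full precision; half-up rounding only
  at reporting (2 dp for unit prices, nearest integer for aggregates), which
  reproduces printed-table conventions such as €20.92 → £17.78 and
  €11,285 → £9,592.

## Synthetic cohort generator

The generator emulates the study conditions so the pipeline can be validated
without patient data. Defaults (all configurable through `CohortParams`):

* **Design:** 64 participants per arm; age ~ N(48, 10²) years, baseline
  depressive score ~ N(15, 8²) (clipped to a questionnaire range), gross
  daily wage ~ N(150, 35²) EUR/day.
* **Remission:** Bernoulli per arm, P = 0.42 (intervention) vs 0.06
  (control); final ISI drawn below/above the cutoff accordingly, baseline ISI
  above the trial's inclusion threshold (≥ 15).
* **Utilities:** truncated-normal baseline (mean 0.70, SD 0.08, lower with
  higher depressive burden at 0.03/SD), a linear intervention effect from
  baseline to 6 months sized so the expected QALY increment is 0.019, and
  measurement noise (SD 0.05), all clipped to [0, 1].
* **Costs:** each category is two-part — Bernoulli "any use" × gamma
  magnitude with coefficient of variation 1 — with unconditional means equal
  to the published arm-level 6-month category means, split evenly across
  recall windows, and a multiplicative mean-one dependence on depressive
  burden (`exp(0.2·z − 0.02)`). Resource-use *counts* are derived by dividing
  the drawn cost by the unit price, so costing a generated record reproduces
  the drawn cost exactly; counts are therefore continuous intensities, not
  integers. The garbled published control-arm domestic-help mean is set to
  €295 so the printed incremental (+€15) is respected.
* **Presenteeism decomposition:** inefficiency ~ U(0.2, 0.6); when a drawn
  cost would imply more impaired days than the window's 65 workdays, days are
  capped and the inefficiency raised to preserve the cost (truncating only
  the negligible full-loss tail). HLQ hours are a fixed recoverable share
  (0.3) of the Osterhaus loss, making the HLQ estimate strictly lower.
* **Dropout:** 12% at follow-up, missing at random given baseline depressive
  burden (logistic, 0.5 log-odds per SD, intercept calibrated so the cohort
  mean equals the configured rate). Dropout removes the 6-month ISI, the
  6-month utility and all post-baseline resource use; baseline fields are
  never removed. Cohorts generated with different dropout rates share the
  same underlying complete data (separate seed streams), which the
  imputation tests exploit.

What the generator does **not** emulate: item-level questionnaire responses,
correlation between clinical response and cost trajectories (cost means are
arm-specific but independent of remission), non-monotone missingness
patterns, and any seasonal or calendar structure. Passing tests therefore
demonstrate that the *pipeline* is correct and calibrated, not that the
original trial's conclusions are reproduced from its raw data (which were
never deposited). The number of recall windows covering the 6-month
accumulation is an explicit assumption (default 2 × 3 months) because the
administration schedule of the cost questionnaire is not published.

## Estimation

* **Imputation.** Missing follow-up costs, utilities and ISI scores are
  replaced by predicted means from per-column OLS regressions on the
  intervention indicator plus predictors of outcome (baseline utility and
  ISI) and of dropout (baseline depressive score, age). Deterministic — no
  residual draws. Predictions are clipped to valid ranges (utilities [0, 1],
  ISI [0, 28], costs ≥ 0). A consequence worth knowing: dichotomizing a
  deterministically imputed ISI attenuates the intention-to-treat risk
  difference, because predicted means rarely cross the cutoff.
* **Cost model.** A gamma-family identity-link GLM (IRLS, started from OLS)
  captures the skewness of costs with additive covariate effects; the
  modified Park test (slope of log squared residuals on log fitted values)
  guides the family choice, recommending gamma when variance ∝ mean². Zero
  costs are lifted to a €0.01 floor; if more than 20% of costs are zero the
  fit falls back to gaussian OLS, since the gamma likelihood is undefined at
  zero.
* **SUR.** The joint incremental estimate comes from a two-equation
  seemingly unrelated regression fitted by one-step feasible GLS: OLS per
  equation, 2×2 residual covariance (divisor n), then GLS on the stacked
  system. With identical regressor sets the FGLS solution reduces exactly to
  per-equation OLS (Kruskal). A degenerate residual covariance with
  essentially zero residuals (e.g. perfectly replicated participants) falls
  back to the OLS solution, which is exact there; a singular covariance with
  non-trivial residuals raises. Default equations: cost ~ arm + age +
  baseline depression; QALY ~ arm + baseline utility; symptom-free ~ arm.
* **Bootstrap.** Participants are the resampling unit; B = 2500 replicates
  (configurable, ≥ 100). The deterministic imputation is re-run inside every
  replicate (and every jackknife leave-one-out sample), so imputation
  uncertainty propagates into the cloud; without this the intervals are
  anti-conservative. Replicates with singular resampled systems are redrawn
  to keep B exact; more than 5% failures aborts with diagnostics. The solver
  evaluates whole batches of index sets with einsum-based normal equations,
  which keeps a full 2500-replicate evaluation below a second.
* **Intervals.** BCa intervals for ΔC and ΔE: bias correction z₀ from the
  fraction of replicates below the point estimate, acceleration a from
  jackknife skewness; with z₀ = a = 0 the interval reduces to the percentile
  interval. All-identical replicates yield a degenerate interval with a
  warning.

## Decision analytics

* **ICER.** Reported as the ratio of point-estimate ΔC to point-estimate ΔE
  (the bootstrap mean of per-replicate ratios is available behind a flag but
  is unstable when replicate effects approach zero). ΔC < 0 with ΔE > 0 sets
  the *dominant* flag and suppresses the ratio in reports.
* **Acceptability CI for the ICER.** Replicates are ordered by angle on the
  cost-effectiveness plane, counterclockwise from the south axis (pure cost
  saving), so the ordering runs SE (dominant) → NE (increasing ICER) → NW
  (dominated) and respects dominance; the interval endpoints are the ICERs of
  the replicates at the (1 ∓ level)/2 positions. Endpoints can legitimately
  be negative when the cloud spans quadrants.
* **Quadrants.** ΔE = 0 counts as "not more effective" (west), ΔC = 0 as
  "not more costly" (south); for continuous clouds the convention is
  cosmetic. Percentages are exact before any report rounding and sum to 100.
* **CEAC.** P(λ·ΔE − ΔC > 0) over a willingness-to-pay grid (default 0 to
  50,000 by 250 €/QALY, or 0 to 5,000 by 50 € per symptom-free status). Ties
  (NMB exactly 0) count as *not* cost-effective — conservative and
  measure-zero for continuous clouds.

## Scenario grid

`sensitivity_grid()` reproduces the 11 published variants: HLQ presenteeism
(societal), intervention price × {0.8, 1.2, 0.5, 1.5} under both
perspectives, and completers-only under both perspectives. Completers
analyses drop incomplete participants instead of imputing; requesting
imputation together with the completers sample is a configuration error.
Per-scenario seeds derive deterministically from a master seed, so the whole
table is byte-reproducible. Two exact structural identities hold and are
tested: scaling the intervention price shifts every replicate's incremental
cost by exactly the price change (the added term is collinear with the arm
indicator, so FGLS weights are unchanged), and with a shared covariate set in
both equations the societal-minus-public incremental cost equals the
patient/family + productivity incremental cost replicate by replicate. With
different covariate sets per equation the second identity is only approximate,
because the feasible weights depend on the cost response.

## Problem sizes used in validation

Calibration and recovery checks run at n = 10,000 per arm (component means,
QALY gain, SUR and gamma-GLM parameter recovery within two standard errors).
Interval calibration uses 200 simulated trials at the study's own size
(n = 64 per arm) with B = 500 bootstrap replicates, requiring ≥ 90% empirical
coverage of nominal 95% BCa intervals for both incremental cost and QALYs.
Full evaluations in examples and the acceptance script use B = 2500.

## Limitations

* The generator's cost components are independent of clinical response, so
  cost–effect residual correlation is near zero under defaults; the SUR's
  cross-equation machinery is validated on separately simulated correlated
  systems.
* Deterministic regression imputation understates within-imputation
  uncertainty relative to multiple imputation; re-imputing within the
  bootstrap restores interval calibration for means, but the thresholded
  symptom-free outcome remains attenuated under imputation (see above).
  Completers-only scenarios provide the complementary view.
* The acceptability-interval angular convention is one of several in use;
  it is documented above and oracle-tested for internal consistency.
* Printed-table reproduction is limited to arithmetic identities (totals,
  conversions, remission fractions): replicate-level published results (CIs,
  quadrant percentages, CEAC values) are not reproducible without the
  original patient-level data.
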