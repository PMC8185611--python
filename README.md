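# trialcea

Trial-based cost-effectiveness and cost-utility analysis for two-arm
randomized trials, built around the health-economic evaluation of a guided
internet-based cognitive behavioural therapy for insomnia (iCBT-I) against a
wait-list control. The package is for health economists and trial
statisticians who need the full evaluation pipeline — per-participant costing
from resource-use records, QALY and symptom-free outcomes, covariate-adjusted
incremental estimates with bootstrap uncertainty, and decision-analytic
summaries — as reusable, tested Python components rather than a one-off
analysis script.

Because individual patient data for the motivating trial were never
deposited, the package ships a synthetic cohort generator calibrated to the
trial's published arm-level statistics (2 × 64 schoolteachers, 42% vs 6%
remission, a 0.019 QALY gain, right-skewed cost components, ~12% dropout), so
every stage of the pipeline is exercised and validated end to end.

## The method

For intervention (INT) and control (CTR) arms, the incremental
cost-effectiveness ratio is

```
ICER = (Cost_INT − Cost_CTR) / (Effect_INT − Effect_CTR) = ΔC / ΔE
```

with effects measured either as symptom-free status (Insomnia Severity Index
score < 8) or as QALYs (trapezoid area under linearly interpolated SF-6D
utilities over 0.5 years). Costs are valued from resource-use records with
2013 German guideline unit prices (consumer-price-index factor 1.04,
convertible to GBP at purchasing power parity £0.85/€), under a societal
perspective (direct medical + patient/family + productivity costs) or a
public-health-care perspective (direct medical only). Absenteeism follows the
human capital approach; presenteeism the Osterhaus method, with the HLQ
recoverable-hours method as a sensitivity variant.

Incremental costs and effects are estimated jointly by a two-equation
seemingly unrelated regression (feasible GLS with cross-equation residual
correlation): the cost equation adjusts for age and baseline depressive
symptoms, the QALY equation for baseline utility. Sampling uncertainty is
propagated by a nonparametric participant-level bootstrap (2500 replicates)
of the whole estimation pipeline — including the deterministic regression
imputation of missing follow-up costs and utilities, which is re-run inside
every replicate. Bias-corrected and accelerated (BCa) intervals summarize ΔC
and ΔE; the ICER interval uses the bootstrap acceptability (angular-quantile)
method; the replicate cloud yields the cost-effectiveness plane quadrant
distribution and acceptability curves `P(λ·ΔE − ΔC > 0)` over a
willingness-to-pay grid λ.

## Worked example

```python
from trialcea import CohortParams, ScenarioConfig, generate_cohort, run_scenario

cohort = generate_cohort(CohortParams(seed=1))          # 2 x 64 participants
societal = run_scenario(cohort, ScenarioConfig(
    perspective="societal", outcome="qaly", B=2500, seed=2))
```

Running `python examples/04_evaluate.py` (which does exactly this) prints:

```
societal perspective, QALY outcome
  delta cost:       -362 EUR (95% BCa CI -1347 to 567)
  delta effect:   0.0162 QALYs (95% BCa CI 0.0113 to 0.0215)
  ICER: dominant
  plane distribution: {'NE': 25, 'NW': 0, 'SE': 75, 'SW': 0}

public health care perspective, QALY outcome
  delta cost:        241 EUR
  ICER: 14847 EUR per QALY (acceptability CI 6191 to 26870)
  P(cost-effective) at WTP 20 000 EUR/QALY: 0.83
```

Read: on this simulated cohort the intervention saves €362 per participant
from the societal perspective while gaining 0.016 QALYs, so it *dominates*
the control (75% of bootstrap replicates fall in the south-east quadrant of
the cost-effectiveness plane). From the payer's perspective the intervention
price makes it €241 more expensive, buying health at €14,847 per QALY — an
83% probability of being cost-effective at a €20,000/QALY threshold. Exact
values vary with the cohort and bootstrap seeds; at n = 64 per arm the
incremental cost carries a standard error of several hundred euros.

The other scripts in `examples/` walk through cohort simulation, costing,
outcome computation, and the 11-scenario sensitivity grid. A thin CLI wraps
the same functions:

```bash
trialcea simulate --seed 1 --out cohort.csv
trialcea evaluate --cohort cohort.csv --seed 2 --out-dir results/
trialcea sensitivity --cohort cohort.csv --seed 5 --out-dir results/
```

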