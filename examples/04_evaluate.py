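"""Full economic evaluation of one scenario: bootstrapped SUR, BCa intervals,
ICER, cost-effectiveness plane, and the acceptability curve.
"""

from trialcea import CohortParams, ScenarioConfig, generate_cohort, run_scenario

cohort = generate_cohort(CohortParams(seed=1))

societal = run_scenario(cohort, ScenarioConfig(
    scenario_id="societal_qaly", perspective="societal", outcome="qaly",
    B=2500, seed=2))
print("societal perspective, QALY outcome")
print(f"  delta cost:   {societal.delta_cost:8.0f} EUR "
      f"(95% BCa CI {societal.delta_cost_ci[0]:.0f} to {societal.delta_cost_ci[1]:.0f})")
print(f"  delta effect: {societal.delta_effect:8.4f} QALYs "
      f"(95% BCa CI {societal.delta_effect_ci[0]:.4f} to {societal.delta_effect_ci[1]:.4f})")
print(f"  ICER: {societal.icer.report()}")
print(f"  plane distribution: { {k: round(v) for k, v in societal.quadrants.items()} }")

public = run_scenario(cohort, ScenarioConfig(
    scenario_id="public_qaly", perspective="public_health_care", outcome="qaly",
    B=2500, seed=3))
print("\npublic health care perspective, QALY outcome")
print(f"  delta cost:   {public.delta_cost:8.0f} EUR")
print(f"  ICER: {public.icer.report()} EUR per QALY "
      f"(acceptability CI {public.icer_ci[0]:.0f} to {public.icer_ci[1]:.0f})")
print(f"  P(cost-effective) at WTP 20 000 EUR/QALY: {public.ceac_at(20_000):.2f}")
# A dominant societal result means the intervention is cheaper AND more
# effective; from the payer perspective the intervention price buys health at
# the printed ICER, and the CEAC shows how the decision depends on the
# willingness to pay per QALY.
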