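"""Value one participant's resource use under both perspectives.

Unit prices are 2013 German guideline prices; presenteeism can be valued by
the Osterhaus method (impaired days x inefficiency x wage) or the lower-bound
HLQ recoverable-hours method.
"""

from trialcea import (
    ResourceUse,
    UnitCostTable,
    aggregate,
    convert_eur_to_gbp,
    cost_participant,
)
from trialcea.cohort import ParticipantRecord

table = UnitCostTable()
record = ParticipantRecord(
    id="demo", arm="intervention", age=48, baseline_depression=15,
    gross_daily_wage=150.0,
    isi=(19, 12, 6), utility=(0.70, 0.74, 0.78),
    resource_use=[
        ResourceUse(gp_visits=2, psychotherapist_sessions=3, travel_km=40,
                    absenteeism_days=2, presenteeism_days=8, inefficiency_score=0.4,
                    hours_to_recover=6.0, medication_ddd={"antidepressant": 30}),
        ResourceUse(gp_visits=1, informal_care_hours=5, out_of_pocket=25.0),
    ],
)

breakdown = cost_participant(record, table)
for category, eur in breakdown.as_dict().items():
    if eur:
        print(f"{category:>15}: {eur:8.2f} EUR")
public = aggregate(breakdown, "public_health_care")
societal = aggregate(breakdown, "societal")
print(f"\npublic health care total: {public:8.2f} EUR ({convert_eur_to_gbp(public, aggregate=True):.0f} GBP)")
print(f"societal total:           {societal:8.2f} EUR ({convert_eur_to_gbp(societal, aggregate=True):.0f} GBP)")

hlq = cost_participant(record, table, presenteeism_method="hlq")
print(f"\npresenteeism, Osterhaus: {breakdown.presenteeism:.2f} EUR; "
      f"HLQ: {hlq.presenteeism:.2f} EUR (recoverable share only)")
# The public perspective keeps direct medical costs only; the societal total
# adds patient/family and productivity costs, here dominated by lost workdays.
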