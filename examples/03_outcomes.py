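"""The two health outcomes: symptom-free status and QALYs.

Symptom-free means an Insomnia Severity Index score strictly below 8. QALYs
integrate linearly interpolated SF-6D utilities over the 6-month horizon.
"""

from trialcea import UtilityTrajectory, qaly_auc, symptom_free_status

for score in (5, 7, 8, 15):
    print(f"ISI {score:>2} -> symptom-free: {symptom_free_status(score)}")

flat = UtilityTrajectory((0.0, 0.5), (0.72, 0.72))
improving = UtilityTrajectory((0.0, 8 / 52, 0.5), (0.70, 0.73, 0.78))
print(f"\nconstant utility 0.72 over half a year: {qaly_auc(flat):.3f} QALYs")
print(f"improving trajectory 0.70 -> 0.78:      {qaly_auc(improving):.4f} QALYs")
print(f"difference:                             "
      f"{qaly_auc(improving) - qaly_auc(flat):.4f} QALYs")
# A few hundredths of a QALY over six months is the realistic effect size for
# an insomnia intervention; the trapezoid rule makes the AUC exact for
# piecewise-linear utility paths.
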