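"""The economic reporting surface on externally known totals.

When five-year per-member totals and the population savings decomposition
are known (e.g. from a published evaluation), the economics layer reproduces
the derived figures: net savings, ROI, monthly views and QALY-day
conversion. Here the inputs are the published totals of a workplace
behavioral-care evaluation.
"""

import cardioroi as cr

net = cr.compute_total_savings(
    medication_savings=9_880_784,
    services_savings=23_055_163,
    program_costs=4_371_780,
)
roi = cr.compute_roi(net, 4_371_780)
print(f"net savings:  ${net:,.0f}  (medication + services - program)")
print(f"ROI:          {roi:.2f}  (dollars saved per program dollar)")

config = cr.ScenarioConfig(
    horizon=5, population=4461, baseline_distribution={"healthy": 1.0}
)
treated = cr.CohortTrace.from_totals(41_431, 4.7, 5, arm=cr.INTERVENTION)
control = cr.CohortTrace.from_totals(47_834, 4.6, 5)
summary = cr.summarize(treated, control, config)
rep = summary.rounded_report()

print(f"per-member saving: ${summary.per_member_saving:,.0f} over 5 years")
print(f"monthly per member: ${rep['monthly_cost_per_member']['treated']} vs "
      f"${rep['monthly_cost_per_member']['control']} "
      f"(difference ${rep['monthly_cost_per_member']['difference']})")
print(f"QALY gain: {summary.qaly_gain:.1f} = "
      f"{summary.qaly_gain_days:.1f} days of full health")
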