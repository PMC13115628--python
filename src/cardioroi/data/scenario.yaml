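# Packaged default scenario.
#
# The baseline state distribution and intervention effect multipliers below
# are ILLUSTRATIVE: the only published anchors are the 23.5% baseline
# hypertension prevalence and the program's default $720 annual cost. The
# remaining prevalences and all relative-risk multipliers are plausible
# working-age defaults, clearly not measured program effects. Replace them
# with population- and program-specific values for any real analysis.
start_age: 40
horizon: 5
discount_rate: 0.03
population: 4461
program_cost_per_member_year: 720.0
medication_savings_fraction: 0.30   # presentational split, ILLUSTRATIVE
baseline_distribution:              # ILLUSTRATIVE except htn (0.235, published)
  healthy: 0.365
  obesity: 0.15
  pre_dm: 0.10
  pre_htn: 0.05
  htn: 0.235
  dm: 0.05
  dm_htn: 0.02
  ob_htn: 0.02
  ob_dm: 0.01
intervention_rrr:                   # ILLUSTRATIVE relative-risk multipliers
  healthy->obesity: 0.7
  healthy->pre_dm: 0.7
  healthy->pre_htn: 0.7
  obesity->pre_dm: 0.7
  obesity->dm: 0.7
  pre_dm->dm: 0.7
  pre_dm->hr_dm: 0.7
  pre_htn->htn: 0.7
  htn->htn2: 0.7
  dm->hr_dm: 0.7
  dm_htn->hr_dm: 0.7
  ob_htn->ob_htn_dm: 0.7
  ob_dm->ob_htn_dm: 0.7
  ob_htn_dm->hr_dm: 0.7
  ANY->cad: 0.9
  ANY->mi: 0.9
  ANY->chf: 0.9
  ANY->stroke: 0.9
psa:
  n_iter: 10000
  seed: 0
  percentiles: [2.5, 97.5]
  rrr_sigma: 0.1
tornado:
  program_cost_per_member_year: [360.0, 1440.0]
  discount_rate: [0.0, 0.06]
  cost:dm: [4750.0, 14250.0]
  prob:pre_dm->dm: [0.0056, 0.0224]
  rrr:pre_dm->dm: [0.5, 1.0]
notes: >-
  Packaged default scenario; baseline_distribution (except htn) and
  intervention_rrr are ILLUSTRATIVE defaults, not published program effects.
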