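"""One-way (tornado) sensitivity of ROI on the packaged default scenario.

Each named parameter is set to its low and high bound in turn, all others at
base case; parameters are ranked by the resulting ROI swing.
"""

import cardioroi as cr

states = cr.default_state_table()
transitions = cr.default_transition_table(states)
life = cr.default_life_table()
config = cr.load_scenario(cr.default_scenario_path())

result = cr.run_tornado(config, states, transitions, life)
print(f"base-case ROI: {result.base_roi:.2f}")
print(f"{'parameter':35s} {'low':>10s} {'high':>10s} {'ROI@low':>8s} "
      f"{'ROI@high':>9s} {'swing':>6s}")
for e in result.entries:
    print(f"{e.name:35s} {e.low_value:10.4g} {e.high_value:10.4g} "
          f"{e.roi_at_low:8.2f} {e.roi_at_high:9.2f} {e.swing:6.2f}")
print()
print("Widest bars are the parameters whose uncertainty moves ROI the most;")
print("program cost always ranks high because it is the ROI denominator.")
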