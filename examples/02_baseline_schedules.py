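"""Build the two naive baseline schedules for the nine equal-curve
evaluation scenarios and print their totals side by side."""

from rehabgym import best_robot_schedule, switch_halfway_schedule, total_gain
from rehabgym.evaluation import equal_curve_suite

print(f"{'Scenario':<26}{'best robot':>12}{'switch halfway':>16}")
for tag, scenario in equal_curve_suite():
    br = total_gain(scenario, best_robot_schedule(scenario))
    sw = total_gain(scenario, switch_halfway_schedule(scenario))
    print(f"{tag:<26}{br:>12.1f}{sw:>16.1f}")
print("\nSwitching halfway always beats staying put: with concave skill"
      "\ncurves, two half-sessions on different robots outgain one full"
      "\nsession on the best robot.")
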