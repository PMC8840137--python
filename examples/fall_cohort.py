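"""Generate a synthetic fall-detection cohort and inspect its structure.

The default configuration emulates a wearable-sensor fall study: 14
subjects x (20 fall actions + 16 activities of daily living) x 5
repetitions = 2520 trials, each summarized by 216 features from 6 body
positions x 3 tri-axial devices x 4 statistics per channel.
"""

from medivote import FallCohortConfig, generate_fall_cohort

cfg = FallCohortConfig(seed=1)
table = generate_fall_cohort(cfg)

print(f"trials:   {table.n_rows}  (= {cfg.n_subjects} subjects x "
      f"{cfg.n_fall_actions}+{cfg.n_adl_actions} actions x "
      f"{cfg.repetitions} repetitions)")
print(f"features: {cfg.n_features}  (= {cfg.n_units} units x "
      f"{cfg.devices_per_unit} devices x {cfg.axes_per_device} axes x "
      f"{cfg.stats_per_channel} stats)")

counts = {}
for v in table.column("action_class"):
    counts[v] = counts.get(v, 0) + 1
print(f"class balance: {counts}")
print("first feature columns:", table.attributes[:4])
print("auxiliary column 'action_id' names the movement; drop it to model "
      "from sensor features alone.")
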