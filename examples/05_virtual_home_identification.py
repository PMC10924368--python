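"""End-to-end BPSD identification in the virtual home.

120 generated manifestation samples are realized as scripted walks in
three rooms (40 per room): the walking-speed level becomes a concrete
m/s value, wandering becomes a lapping or pacing route.  The robot
follows with the fuzzy controller, detects speed and wandering, fills in
the assumed-known context (time, environment, HRV, daytime activity),
and a trained BePhyEn tree predicts the label.  Expect ~80% overall;
lost targets count as failures.
"""

from bpsdmon import run_identification_experiment
from bpsdmon.datagen import generate_dataset, variant_table
from bpsdmon.models import train_tree

model = train_tree(generate_dataset(variant_table("bephyen"), seed=0), seed=0)
result = run_identification_experiment(model, seed=1)

print(result.summary())
print("\nPer-room accuracy:")
print(result.rows.groupby("room")["correct"].mean().round(3).to_string())
print("\nFirst rows:")
cols = ["room", "true_label", "speed_mps", "detected_level",
        "wandering_truth", "wandering_detected", "predicted", "correct"]
print(result.rows[cols].head(8).to_string(index=False))
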