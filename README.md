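# bpsdmon

Modeling and simulated home monitoring of **behavioral and psychological
symptoms of dementia** (BPSD): agitation, apathy, and depression.

Dementia care increasingly needs ways to notice symptomatic episodes *at
home*, between clinical assessments. `bpsdmon` implements a complete,
self-contained study of that problem for researchers in digital health and
assistive robotics:

1. **Regularity tables** — literature-derived admissible level ranges for
   each (factor, BPSD type, severity) cell, for two factor families:
   *PsyCo* (8 psycho-cognitive factors a caregiver can observe: impaired
   communication, somatic diseases, MMSE, weight loss, loss of insight,
   stressful events, self-esteem, anxiety) and *BePhyEn* (6
   behavior/physiology/environment manifestations a sensor platform can
   measure: time of day, environmental change, walking speed, heart-rate
   variability, daytime activity, wandering).
2. **Synthetic data generation** — labeled datasets drawn uniformly within
   those ranges (per BPSD type: 20 high + 10 mild + 10 none; 120 samples
   by default, 30 per class with labels 0 = agitation, 1 = apathy,
   2 = depression, 3 = no BPSD).
3. **Decision-tree classifiers** — CART trees (Gini impurity, at most 20
   splits) for four feature-set variants: PsyCo, PsyCo+HRV, BePhyEn, and
   BePhyEn without HRV, with evaluation (accuracy, confusion, macro
   one-vs-rest AUC), JSON serialization, and a sample-size study.
4. **A 2D virtual home** — three room fixtures with furniture occlusions,
   a scripted elderly target, and a disc robot with a line-of-sight
   range/bearing sensor; three person-following controllers, including a
   Mamdani fuzzy controller that follows closer when the target is faster
   or further off the vision center.
5. **Perception and end-to-end evaluation** — target position by
   triangulation (`XT = XR + d·cos θ`, `YT = YR + d·sin θ`), walking speed
   as per-second displacement with a 5-s moving mean, wandering detection
   by in-order marker-rectangle traversal (4 circles), and the full
   simulate → perceive → predict identification experiment.

## Worked example

```python
from bpsdmon import train_eval_variant, run_identification_experiment
from bpsdmon.datagen import generate_dataset, variant_table
from bpsdmon.models import train_tree

# validation accuracy of the sensor-side model
model, report = train_eval_variant("bephyen", seed=0)
print(report.accuracy)          # ~0.85-0.88 depending on the seed

# full virtual-home pipeline over 120 samples in three rooms
result = run_identification_experiment(model, seed=1)
print(result.summary())
```

Running `python examples/02_train_models.py` prints (seeds 0–4):

```
psyco          validation accuracy  81.7% (5 seeds)
psyco_hrv      validation accuracy  93.5% (5 seeds)
bephyen        validation accuracy  85.3% (5 seeds)
bephyen_nohrv  validation accuracy  83.0% (5 seeds)

BePhyEn tree: root split on 'hrv' (threshold 1.50), 19 internal nodes
```

The ordering is the substantive finding: HRV is the single most
informative manifestation (an HRV level below 1.5 immediately indicates
depression), walking speed ranks next, and a PsyCo model augmented with
HRV clearly beats every other variant.
`python examples/05_virtual_home_identification.py` runs the end-to-end
experiment and prints ~78–83% identification accuracy, with the cramped
room 2 (pacing wandering, more occlusions) as the weakest room — speed
read through pacing reversals biases low, exactly the failure mode a real
follower robot exhibits.

The other examples cover data generation (`01`), the sample-size study
(`03`, accuracy/AUC rising from n=60 to n=480), and the following-
algorithm benchmark (`04`, the band and fuzzy followers beat constant
following on power consumption).

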