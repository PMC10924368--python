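"""Train the four decision-tree BPSD classifiers and compare them.

Each variant trains on a fresh 120-sample set and is scored on an
independently generated set with the same composition.  Expect roughly
83 / 92 / 87 / 81 percent for PsyCo, PsyCo+HRV, BePhyEn, BePhyEn-HRV:
adding heart-rate variability helps, removing it hurts.
"""

import numpy as np

from bpsdmon import train_eval_variant
from bpsdmon.datagen import generate_dataset, variant_table
from bpsdmon.models import train_tree

for kind in ("psyco", "psyco_hrv", "bephyen", "bephyen_nohrv"):
    accs = [train_eval_variant(kind, seed)[1].accuracy for seed in range(5)]
    print(f"{kind:14s} validation accuracy {100 * np.mean(accs):5.1f}% "
          f"(5 seeds)")

model = train_tree(generate_dataset(variant_table("bephyen"), seed=0), seed=0)
print(f"\nBePhyEn tree: root split on {model.root_feature!r} "
      f"(threshold {model.root_threshold:.2f}), "
      f"{model.n_internal_nodes} internal nodes")
print(model.render_text()[:400], "...")
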