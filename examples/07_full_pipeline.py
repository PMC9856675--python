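"""Run all eight pipeline stages end to end into a run directory.

Equivalent to the CLI:  rtspect run-all --seed 0 --out demo_run
Each stage persists its artifact plus a JSON manifest with parameters,
derived seed, input hashes and in/out counts.
"""

import json
from pathlib import Path

import rtspect as r

cfg = r.PipelineConfig(out_dir="scratch/demo_run", seed=0,
                       n_subjects=3, trials_per_subject=120,
                       r=15, n_iterations=40, epochs=6,
                       conv_filters=(6, 12), fc_units=(24,))
run = r.run_pipeline(cfg)

print(f"run directory: {run}")
for stage in ("synth", "cluster", "augment", "filter", "topomap", "train",
              "saliency", "stats"):
    man = json.loads((run / f"manifest_{stage}.json").read_text())
    print(f"  {stage:8s} {man['counts']}")
# Counts reconcile across stages: augment out = filter in, filter out =
# topomap in, and the activation table has 64 x 3 rows per test image.
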