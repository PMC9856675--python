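"""Tree-structured Parzen estimator search over a toy objective.

TPE proposes each new trial by maximizing the density ratio l(x)/g(x)
between Parzen estimates fitted to the best gamma-quantile of past trials
and to the rest. The decoder search space (depth, filter widths, FC width,
dropout, learning rate, optimizer) is ``decoder_space()``; the published
experiment ran 73 trials. Here a 1-D quadratic keeps the example instant.
"""

import numpy as np

import rtspect as r
from rtspect.tpe import DEFAULT_BUDGET, tpe_search

space = {"x": r.Uniform(0.0, 1.0)}
target = 0.31


def objective(params):
    return -(params["x"] - target) ** 2


best, log = tpe_search(space, budget=30, objective=objective, seed=0)
scores = [t["score"] for t in log]
print(f"best x = {best['x']:.4f} (optimum {target}), "
      f"best score = {max(scores):.6f}")
print(f"mean score, first 10 trials : {np.mean(scores[:10]):.4f}")
print(f"mean score, last 10 trials  : {np.mean(scores[-10:]):.4f}")
# Later trials concentrate near the optimum as the good/bad density ratio
# sharpens.

print("decoder search space:", sorted(r.decoder_space()))
print("published search budget:", DEFAULT_BUDGET, "trials")
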