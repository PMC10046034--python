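"""SMOTE balancing of the two unbalanced sub-experiment cohorts.

The systolic sub-experiment has 68 normotensive vs 48 hypertensive
subjects; the diastolic one 83 vs 143.  Standard SMOTE interpolates each
synthetic sample between a minority point and one of its k nearest
minority neighbors.
"""

import numpy as np

from vasomap.balance import SmoteParams, balance_classes

rng = np.random.default_rng(0)

for name, n_normo, n_hyper in (("systolic", 68, 48), ("diastolic", 83, 143)):
    n = n_normo + n_hyper
    X = rng.normal(size=(n, 17))
    y = np.array(["normotensive"] * n_normo + ["hypertensive"] * n_hyper)
    Xb, yb, source = balance_classes(X, y, SmoteParams(rng_seed=1))
    print(f"{name} sub-experiment: {n_normo} vs {n_hyper} "
          f"-> {(source == 'synthetic').sum()} synthetic samples, "
          f"{len(yb)} subjects total "
          f"({(yb == 'normotensive').sum()} per class)")

print()
print("Balancing adds exactly the class deficit (20 and 60 samples), "
      "giving 136 and 286 subjects; synthetic rows stay flagged so "
      "held-out evaluation can be restricted to originals.")
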