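"""Disease-gene enrichment: recovering a planted odds ratio.

Disease flags are generated so the developmental-lethal (DL) bin has
2.6-fold increased odds of disease association over the 0.20 baseline;
the Wald odds ratio estimated from the flags recovers that value.
"""

import numpy as np
import pandas as pd

from fusil.enrichment import bin_disease_enrichment
from fusil.synthetic_data import generate_disease_flags

rng = np.random.default_rng(1)
genes = [f"g{i}" for i in range(5000)]
bins = dict(zip(genes, rng.choice(["CL", "DL", "SV", "VP", "VN"], size=5000)))
flags = generate_disease_flags(bins, baseline=0.20, true_bin_or={"DL": 2.6}, rng=rng)

assignments = pd.DataFrame({"gene_id": genes, "bin": [bins[g] for g in genes]})
results = bin_disease_enrichment(
    assignments, {"sim": {g for g, f in flags.items() if f}}
)
print(f"{'bin':>4s} {'OR':>6s} {'95% CI':>16s} {'p (BH)':>10s}")
for r in results:
    print(f"{r.group:>4s} {r.or_hat:6.2f} "
          f"[{r.ci_low:6.2f}, {r.ci_high:6.2f}] {r.p_adjusted:10.2e}")
print("\nThe DL bin's estimate sits near the generating value 2.6 with a "
      "significant adjusted Fisher p. The other bins dip below 1 even though "
      "they were generated at baseline: each bin is compared against the "
      "rest of the universe, which contains the enriched DL genes.")
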