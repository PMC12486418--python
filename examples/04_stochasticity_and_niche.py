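"""Normalized stochasticity ratio and Levins niche breadth on the gradient.

NST compares observed pairwise Bray-Curtis dissimilarity within each pond
against a fixed-richness null model; above 50% reads as stochastic-dominated
assembly.  Bcom is the community-mean Levins niche breadth.
"""

import pandas as pd

from halocline import SyntheticSpec, niche_breadth, nst, simulate_gradient_dataset

spec = SyntheticSpec(S=300, n_samples=6, depth=20_000, m=0.1, seed=5)
table, meta = simulate_gradient_dataset(spec)
groups = meta.groups_for(table.sample_ids)

results = nst(table, groups, metric="bray-curtis", n_draws=1000, seed=6)
print("NST per pond (A = purely neutral, D = strongly filtered):")
for pond in "ABCD":
    r = results[pond]
    print(f"  {pond}: NST = {100 * r.nst:5.1f}%  -> {r.classification}")
# NST declines along the gradient: environmental filtering makes observed
# communities more deterministically structured than the null expects.

nb = niche_breadth(table)
bcom = nb.bcom.groupby(pd.Series(groups, index=table.sample_ids)).mean()
print("\nmean Bcom per pond:", bcom.round(2).to_dict())
# Narrower community niche breadth at high salinity is the niche-based
# signature of the same filtering.
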