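"""Disease-gene enrichment with the one-sided Fisher's exact test.

Builds a toy universe with a planted association between a "differentially
expressed" set and a disease list, and contrasts it with an unrelated
control list (as with kidney-trait vs lung-trait GWAS genes).
"""

import numpy as np

from nephroscope import enrichment

rng = np.random.default_rng(8)
universe = [f"G{i:04d}" for i in range(2000)]

disease = list(rng.choice(universe, 150, replace=False))
control = list(rng.choice(universe, 150, replace=False))
# DE genes: half drawn from the disease list, half at random
de_genes = list(rng.choice(disease, 30, replace=False)) + \
           list(rng.choice(universe, 30, replace=False))

for name, gene_list in [("disease", disease), ("control", control)]:
    res = enrichment.fisher_enrichment(de_genes, gene_list, universe)
    print(f"{name:8s} overlap {res.overlap:2d}/{len(de_genes)} DE genes, "
          f"odds ratio {res.odds_ratio:6.1f}, one-sided p = {res.p_value:.2e}")

adjusted = enrichment.bh_adjust([1.1e-20, 0.44])
print(f"BH-adjusted: {adjusted[0]:.1e}, {adjusted[1]:.2f}")
# The planted list is overwhelmingly enriched; the unrelated control list is
# not — the same contrast the kidney vs lung GWAS comparison provides.
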