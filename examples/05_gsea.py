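"""Permutation GSEA between expression-high and expression-low samples.

Genes are ranked by signal-to-noise between the dichotomized groups; a gene set
built from genes shifted in the high group should enrich (positive ES, small
permutation p), while a random set should not.
"""

import numpy as np

from bimeta import (
    GeneSetCollection,
    SyntheticConfig,
    dichotomize_cluster,
    fit_gmm2,
    gsea_permutation,
    simulate_study,
)
from bimeta.dataio import ExpressionDataset

config = SyntheticConfig(n_cohorts=1, n_samples=120, n_null_genes=60, seed=9)
cohort = simulate_study(config).cohorts[0]
ds = cohort.expression

x = ds.gene_values("KYNU")
labels = dichotomize_cluster(x, fit_gmm2(x))

# couple a block of genes to the high group so one set carries real signal
rng = np.random.default_rng(0)
values = ds.values.copy()
coupled = [f"NULL{j:04d}" for j in range(10)]
for g in coupled:
    values[ds.gene_ids.index(g), labels.high_mask] += 1.5
ds = ExpressionDataset(ds.cohort_id, ds.gene_ids, ds.sample_ids, values)

sets = GeneSetCollection(sets={
    "COUPLED_BLOCK": coupled,
    "RANDOM_BLOCK": [f"NULL{j:04d}" for j in range(30, 40)],
})
screen = gsea_permutation(ds, labels.high_mask, sets, n_perm=500, seed=1)
for r in screen.results:
    print(f"{r.set_name:>14}: ES = {r.es:+.2f}, NES = {r.nes:+.2f}, "
          f"p = {r.p_nominal:.3g}, leading edge = {len(r.leading_edge)} genes")

print("\nThe coupled block enriches at the top of the ranking (positive ES, "
      "p at the permutation floor); the random block hovers near ES ~ 0 with "
      "a null p-value.")
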