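"""Pseudobulk PCA with the canonical-correlation permutation test.

Aggregates per-(cluster, sample) pseudobulk profiles, embeds samples by
PCA on concatenated standardized HVG features, and tests association of
the embedding with a sample covariate by permuting the covariate.
"""

import pandas as pd

from festflow.pseudobulk import (
    cc_permutation_test,
    concat_pca,
    make_pseudobulk,
    mana_enriched_clusters,
)
from festflow.simulate import ScSimConfig, simulate_sc

adata, truth = simulate_sc(ScSimConfig(n_cells=2000, n_genes=600, seed=0))
counts = pd.DataFrame(adata.X, index=adata.obs_names, columns=adata.var_names)

profile = make_pseudobulk(counts, adata.obs["cluster"], adata.obs["sample"])
embedding, evr = concat_pca(profile)
print("sample embedding (first 2 PCs):")
print(embedding.iloc[:, :2].round(2).to_string())
print("explained variance ratio:", [round(v, 3) for v in evr[:3]])

covariate = adata.obs.groupby("sample")["response"].first().loc[embedding.index]
res = cc_permutation_test(embedding, covariate, n_perm=10_000, seed=0)
print(f"\nfirst canonical correlation with response: {res.observed_cc:.3f} "
      f"(permutation p = {res.p_value:.4f}, {res.n_perm} perms)")

labels = adata.obs["trb_cdr3"].isin(truth["clone_classes"])
enriched = mana_enriched_clusters(
    adata.obs["cluster"].value_counts(),
    adata.obs.loc[labels, "cluster"].value_counts(),
    fold=2.0,
)
print(f"MANA-enriched clusters (>= 2-fold over background): {enriched}; "
      f"truth: {truth['labelled_clusters']}")
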