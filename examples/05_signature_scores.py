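"""Signature scores and marker genes on a simulated single-cell dataset.

Computes the binned-control checkpoint score, ranks genes correlated
with it, and calls per-cluster marker genes with the documented
rank-sum thresholds.
"""

import pandas as pd

from festflow import log_normalize, run_qc
from festflow.signatures import (
    CHECKPOINT_GENES,
    GeneSet,
    marker_genes,
    module_score,
    score_correlated_genes,
)
from festflow.simulate import ScSimConfig, simulate_sc

adata, truth = simulate_sc(ScSimConfig(n_cells=2000, n_genes=1000, seed=0))
adata_qc = run_qc(adata)
expr = pd.DataFrame(log_normalize(adata_qc),
                    index=adata_qc.obs_names, columns=adata_qc.var_names)

# the simulation has no literal checkpoint genes, so score the simulated
# covariate program instead; checkpoint_score(expr) works identically on
# real data carrying CTLA4/PDCD1/LAG3/HAVCR2/TIGIT/ENTPD1
program = GeneSet("covariate_program",
                  tuple(g for g in truth["de_genes"] if g in expr.columns))
score = module_score(expr, program, seed=0)
by_group = score.groupby(adata_qc.obs["response"]).mean()
print("mean program score by response group:")
print(by_group.round(3).to_string(), end="\n\n")
print(f"(checkpoint score would use {CHECKPOINT_GENES})\n")

top = score_correlated_genes(expr, score, exclude=program, top_k=5)
print("genes most correlated with the score (set excluded):")
print(top[["gene", "correlation"]].round(3).to_string(index=False), end="\n\n")

markers = marker_genes(expr, adata_qc.obs["cluster"])
print(f"{len(markers)} cluster markers; top rows:")
print(markers.sort_values("p_adj").head(5).round(3).to_string(index=False))
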