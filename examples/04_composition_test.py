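"""Test for cell-type composition change of a labelled subset.

The statistic S sums, over cell types, the squared between-timepoint
difference of the subset's representation ratio relative to the
background compartment.  Its null comes from multinomial resampling that
preserves the per-timepoint subset totals; an exact Fisher CxC-by-2 test
runs alongside when the subset is small.
"""

import pandas as pd

from festflow.composition import CompositionCounts, compute_S, monte_carlo_null

# background compartment (all CD8 TIL) and a MANA-specific subset,
# counted per cell type at two timepoints
background = pd.DataFrame(
    {"pre": [400, 300, 300], "post": [420, 280, 300]},
    index=["TRM", "effector", "naive"],
)
subset = pd.DataFrame(
    {"pre": [30, 10, 10], "post": [12, 24, 14]},
    index=background.index,
)

counts = CompositionCounts(background, subset)
print(f"S = {compute_S(counts):.4f}")

res = monte_carlo_null(counts, n_sim=10_000, seed=0)
print(f"Monte-Carlo p = {res.p_value:.4f} ({res.n_sim} sims)")
print(f"Fisher p = {res.fisher_p:.4g} ({res.fisher_method})")
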