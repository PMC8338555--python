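"""Cell-type composition change test for a labelled cell subset between
two timepoints, adjusting for background cell-type abundance.

Let m_ct be the probability that a labelled (e.g. MANA-specific) cell at
timepoint t comes from cell type c, and p_ct the background proportion of
type c at t.  The relative-abundance ratio R_ct = m_ct / p_ct
characterizes where the subset sits relative to the background.  The test
statistic

    S = sum_c (R_c,T1 - R_c,T2)^2

compares H0: R_c,T1 = R_c,T2 for all c against the alternative of a
changed ratio.  Its null distribution is built by Monte-Carlo: the common
ratio R_c is estimated from the two timepoints pooled, and subset cells
at each timepoint are redistributed over types from a multinomial with
probabilities proportional to p_ct * R_c, keeping the per-timepoint
subset totals fixed.  A plain Fisher 2xC homogeneity test is provided as
a companion.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma

import numpy as np
import pandas as pd


@dataclass
class CompositionCounts:
    """Clusters x 2-timepoint counts for the background and the subset.

    Both frames share an index of cell types and exactly two columns
    (timepoints, e.g. W2/W4).
    """

    background: pd.DataFrame
    subset: pd.DataFrame

    def __post_init__(self) -> None:
        self.background = self.background.astype(float)
        self.subset = self.subset.reindex(self.background.index, fill_value=0).astype(float)
        if self.background.shape[1] != 2 or self.subset.shape[1] != 2:
            raise ValueError("exactly two timepoints are required")
        self.subset.columns = self.background.columns

    @property
    def timepoints(self) -> list[str]:
        return list(self.background.columns)

    def proportions(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(p_ct, m_ct): background and subset per-timepoint proportions."""
        p = self.background / self.background.sum(axis=0)
        m = self.subset / self.subset.sum(axis=0)
        return p, m


@dataclass
class CompositionTestResult:
    S_observed: float
    null_S: np.ndarray
    p_value: float
    n_sim: int
    seed: int
    fisher_p: float | None = None
    fisher_method: str | None = None


def _ratios(counts: CompositionCounts) -> pd.DataFrame:
    """R_ct = m_ct / p_ct over types with positive background at both
    timepoints; raises if subset cells sit in a zero-background type."""
    p, m = counts.proportions()
    usable = (p > 0).all(axis=1)
    bad = (~usable) & (counts.subset.sum(axis=1) > 0)
    if bad.any():
        raise ValueError(
            f"subset cells present in types with zero background: {list(counts.subset.index[bad])}"
        )
    return (m[usable] / p[usable])


def compute_S(counts: CompositionCounts) -> float:
    """S = sum_c (R_c,T1 - R_c,T2)^2 over usable cell types."""
    R = _ratios(counts)
    t1, t2 = counts.timepoints
    return float(((R[t1] - R[t2]) ** 2).sum())


def _S_from_subset_matrix(sub: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Vectorized S for simulated subset counts (n_sim x types x 2)."""
    totals = sub.sum(axis=1, keepdims=True)
    m = sub / totals
    R = m / p[None, :, :]
    return ((R[:, :, 0] - R[:, :, 1]) ** 2).sum(axis=1)


def monte_carlo_null(
    counts: CompositionCounts,
    n_sim: int = 10_000,
    seed: int = 0,
    fisher: bool = True,
) -> CompositionTestResult:
    """Monte-Carlo test of H0: R_c,T1 = R_c,T2.

    The pooled common ratio R_c = (pooled subset proportion) / (pooled
    background proportion) is estimated from both timepoints combined;
    each replicate redraws the subset counts at timepoint t from
    Multinomial(n_t, p_ct R_c / sum_c' p_c't R_c'), keeping the observed
    per-timepoint subset totals n_t, and recomputes S.  p-value is the
    add-one upper-tail estimator.
    """
    if counts.background.shape[0] < 2:
        raise ValueError("at least two cell types are required")
    if (counts.subset.sum(axis=0) < 1).any():
        raise ValueError("each timepoint needs at least one subset cell")
    # restrict to types with positive background at both timepoints
    usable = (counts.background > 0).all(axis=1)
    _ = _ratios(counts)  # raises on inconsistency
    bg = counts.background[usable]
    sub = counts.subset[usable]
    p = (bg / bg.sum(axis=0)).to_numpy()          # types x 2
    pooled_bg = bg.sum(axis=1) / bg.sum().sum()
    pooled_sub = sub.sum(axis=1) / sub.sum().sum()
    R_common = (pooled_sub / pooled_bg).to_numpy()
    if not np.any(R_common > 0):
        raise ValueError("degenerate pooled ratio: no subset mass")

    q = p * R_common[:, None]
    q = q / q.sum(axis=0)                          # null multinomial probs per t
    n_t = sub.sum(axis=0).to_numpy().astype(int)

    S_obs = compute_S(counts)
    rng = np.random.default_rng(seed)
    sims = np.empty((n_sim, p.shape[0], 2))
    for j in range(2):
        sims[:, :, j] = rng.multinomial(n_t[j], q[:, j], size=n_sim)
    assert (sims.sum(axis=1) == n_t).all(), "subset totals must be conserved"
    null_S = _S_from_subset_matrix(sims, p)
    p_value = (1 + np.sum(null_S >= S_obs)) / (1 + n_sim)

    fisher_p = fisher_method = None
    if fisher:
        fisher_p, fisher_method = fisher_2xC(counts.subset, seed=seed)
    return CompositionTestResult(
        S_observed=S_obs, null_S=null_S, p_value=float(p_value),
        n_sim=n_sim, seed=seed, fisher_p=fisher_p, fisher_method=fisher_method,
    )


def _log_table_prob(table: np.ndarray, row_lgam: float, col_lgam: float,
                    n_lgam: float) -> float:
    return row_lgam + col_lgam - n_lgam - sum(lgamma(v + 1) for v in table.ravel())


def _enumerate_2col_pvalue(table: np.ndarray) -> float:
    """Exact two-sided Fisher p for a C x 2 table: the probability mass of
    all tables (fixed margins) no more probable than the observed one."""
    rows = table.sum(axis=1).astype(int)
    cols = table.sum(axis=0).astype(int)
    n = int(table.sum())
    row_lgam = sum(lgamma(r + 1) for r in rows)
    col_lgam = sum(lgamma(c + 1) for c in cols)
    n_lgam = lgamma(n + 1)
    obs_lp = _log_table_prob(table, row_lgam, col_lgam, n_lgam)
    total = 0.0
    c1 = int(cols[0])

    def rec(i: int, remaining: int, lp: float) -> None:
        nonlocal total
        if i == len(rows) - 1:
            a = remaining
            if 0 <= a <= rows[i]:
                b = rows[i] - a
                lp_final = lp - lgamma(a + 1) - lgamma(b + 1)
                if lp_final <= obs_lp + 1e-9:
                    total += np.exp(lp_final)
            return
        lo = max(0, remaining - int(rows[i + 1:].sum()))
        hi = min(int(rows[i]), remaining)
        for a in range(lo, hi + 1):
            rec(i + 1, remaining - a,
                lp - lgamma(a + 1) - lgamma(rows[i] - a + 1))
        return

    rec(0, c1, row_lgam + col_lgam - n_lgam)
    return min(total, 1.0)


def fisher_2xC(
    subset_counts: pd.DataFrame,
    max_exact_total: int = 200,
    n_draws: int = 100_000,
    seed: int = 0,
) -> tuple[float, str]:
    """Two-sided Fisher homogeneity test for a C x 2 count table.

    Exact conditional enumeration for tables with total <= ``max_exact_total``;
    otherwise a seeded Monte-Carlo estimate over tables with the observed
    margins (add-one estimator).  All-zero rows are dropped.  Returns
    ``(p, method)``.
    """
    table = np.asarray(subset_counts, dtype=float)
    table = table[table.sum(axis=1) > 0]
    if table.size == 0 or table.sum() == 0:
        raise ValueError("all counts are zero")
    table = table.astype(int)
    if table.shape[0] < 2 or table.sum(axis=0).min() == 0:
        return 1.0, "degenerate"
    if table.sum() <= max_exact_total:
        return _enumerate_2col_pvalue(table), "exact"
    # Monte-Carlo: draw first-column allocation by multivariate hypergeometric
    rows = table.sum(axis=1)
    c1 = int(table.sum(axis=0)[0])
    rng = np.random.default_rng(seed)
    row_lgam = sum(lgamma(r + 1) for r in rows)
    col_lgam = sum(lgamma(c + 1) for c in table.sum(axis=0))
    n_lgam = lgamma(int(table.sum()) + 1)
    obs_lp = _log_table_prob(table, row_lgam, col_lgam, n_lgam)
    draws = rng.multivariate_hypergeometric(rows, c1, size=n_draws)
    second = rows[None, :] - draws
    lgam = lambda arr: np.vectorize(lgamma)(arr + 1)  # noqa: E731
    lps = row_lgam + col_lgam - n_lgam - lgam(draws).sum(axis=1) - lgam(second).sum(axis=1)
    p = (1 + np.sum(lps <= obs_lp + 1e-9)) / (1 + n_draws)
    return float(p), "monte-carlo"
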