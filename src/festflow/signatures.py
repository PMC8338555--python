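"""Gene-set signature scores and marker-gene statistics for single cells.

The central primitive is the binned-control module score: genes are
binned by average expression, and each cell's score for a gene set is the
mean expression of the set minus the mean of expression-matched control
genes sampled from the set genes' bins.  On top of it sit the fixed
six-gene T-cell checkpoint score (CTLA4, PDCD1, LAG3, HAVCR2, TIGIT,
ENTPD1), an exhaustion score from a user-replaceable gene list,
score-correlated gene ranking, thresholded rank-sum marker calling and
dose-response summaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .fest import bh_adjust  # re-exported BH utility (unused here but public)  # noqa: F401

logger = logging.getLogger(__name__)

CHECKPOINT_GENES = ("CTLA4", "PDCD1", "LAG3", "HAVCR2", "TIGIT", "ENTPD1")


@dataclass
class GeneSet:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate symbols")

    @classmethod
    def from_file(cls, path, name: str | None = None) -> "GeneSet":
        with open(path) as fh:
            genes = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
        return cls(name or str(path), tuple(dict.fromkeys(genes)))


def default_exhaustion_set() -> GeneSet:
    """Packaged exhaustion gene list (a synthetic stand-in; replace with a
    published exhaustion signature for real analyses)."""
    path = resources.files("festflow.data") / "exhaustion_genes_synthetic.txt"
    return GeneSet.from_file(path, name="exhaustion")


def module_score(
    expr: pd.DataFrame,
    gene_set: GeneSet,
    bins: int = 24,
    n_controls: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Binned-control composite score of a gene set per cell.

    ``expr`` is cells x genes normalized log expression.  All genes are
    ranked by their average expression across cells and cut into ``bins``
    equal-size bins; for each set gene, ``n_controls`` control genes are
    sampled with replacement from that gene's bin.  The score is
    mean(set genes) - mean(control draws), so a constant added to every
    gene cancels exactly.
    """
    present = [g for g in gene_set.genes if g in expr.columns]
    missing = set(gene_set.genes) - set(present)
    if missing:
        warnings.warn(
            f"{gene_set.name}: {len(missing)} genes absent and dropped: "
            f"{sorted(missing)[:5]}...", stacklevel=2,
        )
    if not present:
        raise ValueError(f"gene set {gene_set.name!r} has no genes in the data")
    if expr.shape[1] < bins:
        raise ValueError(f"need at least {bins} genes to form {bins} bins")
    avg = expr.mean(axis=0)
    bin_of = pd.Series(
        pd.qcut(avg.rank(method="first"), q=bins, labels=False), index=avg.index
    )
    rng = np.random.default_rng(seed)
    genes_by_bin = {b: idx.to_numpy() for b, idx in avg.groupby(bin_of).groups.items()}
    control_cols: list[np.ndarray] = []
    for g in present:
        pool = genes_by_bin[bin_of[g]]
        control_cols.append(rng.choice(pool, size=n_controls, replace=True))
    controls = np.concatenate(control_cols)
    score = expr[present].mean(axis=1) - expr[controls].mean(axis=1)
    score.name = gene_set.name
    return score


def checkpoint_score(expr: pd.DataFrame, seed: int = 0, **kwargs) -> pd.Series:
    """Module score over the six clinically targeted checkpoint genes."""
    missing = [g for g in CHECKPOINT_GENES if g not in expr.columns]
    if missing:
        warnings.warn(f"checkpoint genes absent: {missing}", stacklevel=2)
    return module_score(expr, GeneSet("checkpoint", CHECKPOINT_GENES), seed=seed, **kwargs)


def exhaustion_score(
    expr: pd.DataFrame, gene_set: GeneSet | None = None, seed: int = 0, **kwargs
) -> pd.Series:
    """Module score over an exhaustion gene list (user-supplied or packaged)."""
    gene_set = gene_set or default_exhaustion_set()
    return module_score(expr, gene_set, seed=seed, **kwargs)


def score_correlated_genes(
    expr: pd.DataFrame,
    score: pd.Series,
    exclude: GeneSet | None = None,
    candidates: list[str] | None = None,
    top_k: int = 30,
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Rank genes by Pearson correlation with a per-cell score.

    ``candidates`` restricts the search (e.g. to HVGs); genes in
    ``exclude`` (e.g. the six checkpoint genes when anchoring on the
    checkpoint score) never appear.  Constant genes get correlation 0 and
    ``constant=True``.  When ``groups`` (two labels) is given, per-group
    correlations and their difference are added for the waterfall
    comparison.
    """
    cand = [c for c in (candidates or list(expr.columns)) if c in expr.columns]
    if exclude is not None:
        cand = [c for c in cand if c not in set(exclude.genes)]
    s = score.loc[expr.index].to_numpy(dtype=float)

    def corr_block(mat: pd.DataFrame, vec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = mat.to_numpy(dtype=float)
        xs = X.std(axis=0)
        const = xs == 0
        vec_c = vec - vec.mean()
        Xc = X - X.mean(axis=0)
        denom = np.where(const, 1.0, xs) * (vec.std() if vec.std() > 0 else 1.0)
        r = (Xc * vec_c[:, None]).mean(axis=0) / denom
        r[const] = 0.0
        return r, const

    r, const = corr_block(expr[cand], s)
    out = pd.DataFrame({"gene": cand, "correlation": r, "constant": const})
    if groups is not None:
        levels = pd.Series(groups).loc[expr.index]
        uniq = list(pd.unique(levels.dropna()))
        if len(uniq) != 2:
            raise ValueError("groups must have exactly two levels")
        for lvl in uniq:
            mask = (levels == lvl).to_numpy()
            r_lvl, _ = corr_block(expr.loc[mask, cand], s[mask])
            out[f"correlation_{lvl}"] = r_lvl
        out["correlation_diff"] = out[f"correlation_{uniq[0]}"] - out[f"correlation_{uniq[1]}"]
    out = out.sort_values("correlation", ascending=False, ignore_index=True)
    return out.head(top_k)


def _log2_fold_change(x: np.ndarray, y: np.ndarray) -> float:
    """log2((mean(expm1 x)+1)/(mean(expm1 y)+1)) on log-normalized input."""
    return float(np.log2((np.expm1(x).mean() + 1) / (np.expm1(y).mean() + 1)))


def marker_genes(
    expr: pd.DataFrame,
    groups: pd.Series,
    lfc_min: float = 0.25,
    min_pct: float = 0.25,
    alpha: float = 0.05,
    min_cells: int = 3,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum marker calling with the standard
    thresholds: |log2 fold change| > ``lfc_min`` (upregulated side only),
    expressed in at least ``min_pct`` of the tested group, and Bonferroni
    p < ``alpha`` (corrected over genes tested per group).

    Returns the retained markers with columns ``group, gene, log2_fc,
    pct_group, pct_rest, p_value, p_adj``.
    """
    labels = pd.Series(groups).loc[expr.index]
    out_rows = []
    n_genes = expr.shape[1]
    for grp in pd.unique(labels.dropna()):
        in_grp = (labels == grp).to_numpy()
        if in_grp.sum() < min_cells or (~in_grp).sum() < min_cells:
            warnings.warn(f"group {grp!r} has fewer than {min_cells} cells; skipped",
                          stacklevel=2)
            continue
        X_in = expr.loc[in_grp].to_numpy()
        X_out = expr.loc[~in_grp].to_numpy()
        pct_in = (X_in > 0).mean(axis=0)
        pct_out = (X_out > 0).mean(axis=0)
        for j, gene in enumerate(expr.columns):
            lfc = _log2_fold_change(X_in[:, j], X_out[:, j])
            if lfc <= lfc_min or pct_in[j] < min_pct:
                continue
            res = stats.mannwhitneyu(X_in[:, j], X_out[:, j], alternative="two-sided")
            p_adj = min(1.0, res.pvalue * n_genes)
            if p_adj < alpha:
                out_rows.append({
                    "group": grp, "gene": gene, "log2_fc": lfc,
                    "pct_group": float(pct_in[j]), "pct_rest": float(pct_out[j]),
                    "p_value": float(res.pvalue), "p_adj": float(p_adj),
                })
    return pd.DataFrame(
        out_rows,
        columns=["group", "gene", "log2_fc", "pct_group", "pct_rest", "p_value", "p_adj"],
    )


def rank_sum_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value (exact for small groups),
    exposed for testing marker statistics in isolation."""
    method = "exact" if (len(x) <= 8 and len(y) <= 8) else "auto"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def dose_response_summary(
    scores: pd.Series, dose: pd.Series, group: pd.Series
) -> pd.DataFrame:
    """Mean +/- standard error of a score per (group, dose), with a
    Spearman monotone-trend statistic of score vs log dose per group.

    Rows with fewer than 2 cells are flagged (SEM undefined -> NaN).
    """
    df = pd.DataFrame({"score": scores, "dose": dose, "group": group}).dropna()
    if df["dose"].nunique() < 2:
        raise ValueError("at least two dose levels are required")
    summary = (
        df.groupby(["group", "dose"])["score"]
        .agg(mean="mean", sem=lambda s: s.sem() if len(s) > 1 else np.nan, n="size")
        .reset_index()
    )
    summary["sem_undefined"] = summary["n"] < 2
    trends = []
    for grp, block in df.groupby("group"):
        rho, p = stats.spearmanr(np.log(block["dose"]), block["score"])
        trends.append({"group": grp, "spearman_rho": rho, "spearman_p": p})
    summary = summary.merge(pd.DataFrame(trends), on="group", how="left")
    return summary
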