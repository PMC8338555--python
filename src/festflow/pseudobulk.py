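"""Cluster-level pseudobulk profiles, LOESS-residual HVG selection,
concatenated PCA and the canonical-correlation permutation test.

For each cell cluster, counts are summed across cells within each sample
and normalized to a common library size.  Highly variable genes (HVGs)
are the genes whose across-sample standard deviation exceeds a LOESS fit
of SD against mean.  Each cluster's HVG block is standardized and the
blocks concatenated into one sample x feature matrix; samples are
embedded by PCA and the association of the first two PCs with a sample
covariate (tissue, response status, ...) is assessed by the first
canonical correlation with a label-permutation null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)


@dataclass
class PseudobulkProfile:
    """Per-cluster pseudobulk expression across samples.

    ``values`` maps cluster -> genes x samples DataFrame (columns only for
    samples that contribute cells to that cluster).  ``hvg_sets`` and
    ``concatenated`` are filled by the HVG/PCA steps.
    """

    values: dict[str, pd.DataFrame]
    samples: list[str]
    target_library_size: float
    hvg_sets: dict[str, list[str]] = field(default_factory=dict)
    concatenated: pd.DataFrame | None = None


def make_pseudobulk(
    counts: pd.DataFrame,
    clusters: pd.Series,
    samples: pd.Series,
    target_library_size: float | None = None,
) -> PseudobulkProfile:
    """Aggregate cells x genes ``counts`` into per-(cluster, sample) profiles.

    Each profile is the gene-wise sum over the cluster's cells in that
    sample, scaled so every profile sums to a common library size (the
    mean raw profile total unless given).  Sample/cluster combinations
    with no cells are *missing*, not zero.  Clusters present in fewer
    than two samples are kept in ``values`` but flagged with a warning —
    downstream feature selection drops them.
    """
    clusters = pd.Series(clusters, index=counts.index).astype(str)
    samples = pd.Series(samples, index=counts.index).astype(str)
    sample_ids = sorted(samples.unique())
    grouped = counts.groupby([clusters, samples]).sum()
    totals = grouped.sum(axis=1)
    if target_library_size is None:
        target_library_size = float(totals[totals > 0].mean())
    values: dict[str, pd.DataFrame] = {}
    for cluster in sorted(grouped.index.get_level_values(0).unique()):
        block = grouped.loc[cluster].T  # genes x samples present
        block = block.loc[:, block.sum(axis=0) > 0]
        scaled = block / block.sum(axis=0) * target_library_size
        if scaled.shape[1] < 2:
            warnings.warn(
                f"cluster {cluster!r} present in {scaled.shape[1]} sample(s); "
                "it will be excluded from PCA features",
                stacklevel=2,
            )
        values[cluster] = scaled
    return PseudobulkProfile(
        values=values, samples=sample_ids, target_library_size=target_library_size
    )


def batch_standardize(profile: pd.DataFrame, batches: pd.Series) -> pd.DataFrame:
    """Per-batch centering/scaling of a genes x samples profile — a simple
    batch-effect stand-in (an external correction can be hooked in instead)."""
    out = profile.copy()
    for batch in pd.Series(batches).unique():
        cols = [s for s in profile.columns if batches.get(s) == batch]
        if len(cols) < 2:
            continue
        block = profile[cols]
        sd = block.std(axis=1).replace(0, 1.0)
        out[cols] = block.sub(block.mean(axis=1), axis=0).div(sd, axis=0)
    return out


def select_hvg_loess(
    profile: pd.DataFrame, span: float = 0.3, min_genes: int = 10
) -> list[str]:
    """Genes whose across-sample SD exceeds a LOESS fit of SD vs mean.

    The LOESS is fit on log-transformed means (span 0.3); genes with a
    positive residual are returned.  With fewer than ``min_genes``
    expressed genes the fit is skipped and the top half by SD returned.
    """
    means = profile.mean(axis=1)
    sds = profile.std(axis=1)
    expressed = means > 0
    if expressed.sum() < min_genes:
        warnings.warn("too few expressed genes for LOESS; using top-50% by SD",
                      stacklevel=2)
        keep = sds[expressed].sort_values(ascending=False)
        return list(keep.index[: max(1, len(keep) // 2)])
    x = np.log(means[expressed])
    y = sds[expressed]
    fitted = lowess(y.to_numpy(), x.to_numpy(), frac=span, return_sorted=False)
    resid = y.to_numpy() - fitted
    hvg = y.index[(resid > 0) & (y.to_numpy() > 0)]
    return list(hvg)


def concat_features(
    profile: PseudobulkProfile, span: float = 0.3
) -> pd.DataFrame:
    """Select per-cluster HVGs and build the standardized concatenated
    sample x feature table (features named ``cluster::gene``).

    Clusters missing from any sample are dropped (complete-case) so every
    feature column is fully observed; constant features are dropped.
    """
    blocks = []
    for cluster, block in profile.values.items():
        if set(block.columns) != set(profile.samples):
            logger.info("cluster %r absent from some samples; dropped from features",
                        cluster)
            continue
        hvg = select_hvg_loess(block, span=span)
        profile.hvg_sets[cluster] = hvg
        if not hvg:
            continue
        sub = block.loc[hvg, profile.samples].T
        sub.columns = [f"{cluster}::{g}" for g in hvg]
        blocks.append(sub)
    if not blocks:
        raise ValueError("no complete clusters with HVGs; cannot build features")
    feats = pd.concat(blocks, axis=1)
    sd = feats.std(axis=0, ddof=0)
    feats = feats.loc[:, sd > 0]
    feats = (feats - feats.mean(axis=0)) / feats.std(axis=0, ddof=0)
    profile.concatenated = feats
    return feats


def concat_pca(profile: PseudobulkProfile, n_pcs: int = 2, span: float = 0.3):
    """PCA embedding of samples on the standardized concatenated features.

    Returns ``(embedding, explained_variance_ratio)`` where the embedding
    is a samples x ``n_pcs`` DataFrame (columns PC1, PC2, ...).
    """
    feats = profile.concatenated if profile.concatenated is not None else concat_features(
        profile, span=span
    )
    if feats.shape[0] < 3:
        raise ValueError("PCA requires at least 3 samples")
    pca = PCA(n_components=min(n_pcs, feats.shape[0] - 1, feats.shape[1]),
              svd_solver="full")
    coords = pca.fit_transform(feats.to_numpy())
    embedding = pd.DataFrame(
        coords, index=feats.index,
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return embedding, pca.explained_variance_ratio_


@dataclass
class PermutationResult:
    observed_cc: float
    null_ccs: np.ndarray
    p_value: float
    n_perm: int
    seed: int


def _dummy_code(covariate: pd.Series) -> np.ndarray:
    vals = pd.Series(covariate)
    if vals.nunique() < 2:
        raise ValueError("covariate must take at least 2 distinct values")
    if pd.api.types.is_numeric_dtype(vals) and vals.nunique() > 2:
        return vals.to_numpy(dtype=float).reshape(-1, 1)
    dummies = pd.get_dummies(vals.astype(str), drop_first=True)
    return dummies.to_numpy(dtype=float)


def _first_canonical_correlation(X: np.ndarray, Y: np.ndarray) -> float:
    """First canonical correlation between column-blocks X and Y (centered,
    whitened via pseudo-inverse square roots; robust to rank deficiency)."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    qx, _ = np.linalg.qr(Xc)
    qy, _ = np.linalg.qr(Yc)
    # guard zero columns after centering
    sv = np.linalg.svd(qx.T @ qy, compute_uv=False)
    return float(np.clip(sv.max(initial=0.0), 0.0, 1.0))


def cc_permutation_test(
    embedding: pd.DataFrame,
    covariate: pd.Series,
    n_perm: int = 10_000,
    seed: int = 0,
    strata: pd.Series | None = None,
) -> PermutationResult:
    """Permutation test of the first canonical correlation between the PC
    block (PC1, PC2) and a per-sample covariate.

    The covariate is dummy-coded (so categorical covariates with more
    than two levels work); the null is built by randomly permuting the
    sample labels ``n_perm`` times, optionally within ``strata``.  The
    p-value uses the add-one estimator (1 + #{null >= observed}) /
    (1 + n_perm) and is one-sided (large correlation = association).
    """
    # canonical sample order so results are invariant to input row order
    cov_series = pd.Series(covariate)
    if set(embedding.index) <= set(cov_series.index):
        embedding = embedding.sort_index()
        cov = cov_series.loc[embedding.index]
    else:
        cov = cov_series
    X = embedding.to_numpy(dtype=float)
    Y = _dummy_code(cov)
    observed = _first_canonical_correlation(X, Y)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    if strata is not None:
        strata = pd.Series(strata).reset_index(drop=True)
        groups = [np.flatnonzero(strata == g) for g in strata.unique()]
    null = np.empty(n_perm)
    for i in range(n_perm):
        if strata is None:
            perm = rng.permutation(n)
        else:
            perm = np.arange(n)
            for idx in groups:
                perm[idx] = idx[rng.permutation(len(idx))]
        null[i] = _first_canonical_correlation(X, Y[perm])
    p = (1 + np.sum(null >= observed)) / (1 + n_perm)
    return PermutationResult(observed, null, float(p), n_perm, seed)


def mana_enriched_clusters(
    cluster_sizes: pd.Series, labelled_counts: pd.Series, fold: float = 2.0
) -> list[str]:
    """Clusters where the labelled-cell (e.g. MANA-specific) frequency is at
    least ``fold`` times higher than randomly expected.

    Enrichment of cluster c = (labelled_c / labelled_total) /
    (cells_c / cells_total); clusters with ratio >= fold are returned (to
    be merged into one combined pseudo-cluster downstream).
    """
    cluster_sizes = pd.Series(cluster_sizes)
    labelled = pd.Series(labelled_counts).reindex(cluster_sizes.index, fill_value=0)
    if cluster_sizes.sum() <= 0:
        raise ValueError("cluster sizes must sum to > 0")
    if labelled.sum() <= 0:
        raise ValueError("no labelled cells")
    expected = cluster_sizes / cluster_sizes.sum()
    observed = labelled / labelled.sum()
    ratio = observed / expected
    return list(ratio.index[ratio >= fold])
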