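"""Pseudotime gene-dynamics testing.

Each gene's normalized log expression along a supplied pseudotime is
modelled per sample by a least-squares cubic B-spline f_gs(t) and
compared to a constant (intercept-only) null via a Gaussian likelihood
ratio.  The null distribution of the LR statistic is built by permuting
the pseudotime of cells within each sample, and per-gene p-values are
converted to FDR by Benjamini-Hochberg; genes with FDR < 0.05 are
*dynamic*.  Dynamic genes' mean temporal curves are grouped by k-means
into expression patterns.

Pseudotime itself is an input (any monotone cell ordering rescaled to
[0, 1]); trajectory inference is upstream of this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from sklearn.cluster import KMeans

from .fest import bh_adjust

logger = logging.getLogger(__name__)


def retain_genes(
    expr: pd.DataFrame, min_expr: float = 0.01, min_frac: float = 0.01
) -> list[str]:
    """Genes with normalized expression >= ``min_expr`` in at least
    ``min_frac`` of cells (the dual retention threshold)."""
    frac = (expr >= min_expr).mean(axis=0)
    return list(expr.columns[frac >= min_frac])


def _design_matrix(t: np.ndarray, n_interior_knots: int = 3) -> np.ndarray:
    """Cubic B-spline basis with interior knots at pseudotime quantiles
    (df = 4 + n_interior_knots including the intercept span)."""
    t = np.asarray(t, dtype=float)
    lo, hi = t.min(), t.max()
    if hi <= lo:
        raise ValueError("pseudotime is constant")
    qs = np.linspace(0, 1, n_interior_knots + 2)[1:-1]
    interior = np.quantile(t, qs)
    knots = np.r_[[lo] * 4, interior, [hi] * 4]
    tt = np.clip(t, lo, hi - 1e-12 * max(1.0, abs(hi)))
    return BSpline.design_matrix(tt, knots, 3).toarray()


@dataclass
class SplineFit:
    coefficients: np.ndarray
    fitted: np.ndarray
    rss_alt: float
    rss_null: float
    n: int

    @property
    def lr(self) -> float:
        """Gaussian LR statistic 2*(ll_alt - ll_null) = n*log(rss0/rss1)."""
        if self.rss_alt <= 0:
            return np.inf if self.rss_null > 0 else 0.0
        if self.rss_null <= 0:
            return 0.0
        return max(0.0, self.n * np.log(self.rss_null / self.rss_alt))


def fit_spline(t: np.ndarray, y: np.ndarray, n_interior_knots: int = 3) -> SplineFit:
    """Least-squares cubic B-spline fit of expression on pseudotime, with
    the intercept-only null fit alongside."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    B = _design_matrix(t, n_interior_knots)
    if len(y) < B.shape[1] + 2:
        raise ValueError(f"need at least {B.shape[1] + 2} cells, got {len(y)}")
    coef, *_ = np.linalg.lstsq(B, y, rcond=None)
    fitted = B @ coef
    rss_alt = float(((y - fitted) ** 2).sum())
    rss_null = float(((y - y.mean()) ** 2).sum())
    return SplineFit(coef, fitted, rss_alt, rss_null, len(y))


def evaluate_curve(
    t: np.ndarray, fit: SplineFit, grid: np.ndarray, n_interior_knots: int = 3
) -> np.ndarray:
    """Evaluate a fitted temporal function on a grid (clamped to the fit range)."""
    g = np.clip(grid, t.min(), t.max())
    B = _design_matrix(np.r_[t, g], n_interior_knots)[len(t):]
    return B @ fit.coefficients


@dataclass
class PseudotimeFitResult:
    """Per-gene dynamics test results plus mean temporal curves."""

    table: pd.DataFrame                      # gene, lr, p_value, fdr, dynamic
    curves: pd.DataFrame = field(default_factory=pd.DataFrame)  # genes x grid
    grid: np.ndarray = field(default_factory=lambda: np.linspace(0, 1, 100))
    n_perm: int = 0
    seed: int = 0


def _sample_blocks(samples: pd.Series) -> dict[str, np.ndarray]:
    s = pd.Series(samples).reset_index(drop=True)
    return {str(g): np.flatnonzero(s == g) for g in s.unique()}


def lr_permutation_test(
    expr: pd.DataFrame,
    pseudotime: pd.Series,
    samples: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
    n_interior_knots: int = 3,
    fdr_alpha: float = 0.05,
    curve_grid: int = 100,
) -> PseudotimeFitResult:
    """Permutation LR test of temporal change for every gene.

    The observed statistic is the sum over samples of each sample's
    Gaussian LR (spline vs constant).  The null permutes pseudotime
    within each sample independently per gene and per permutation;
    because the spline design is fixed, permuting pseudotime is
    equivalent to permuting expression, so null statistics come from a
    precomputed orthonormal basis of the design (fast and exact).
    p = (1 + #{null >= observed}) / (1 + n_perm); BH FDR across genes.
    """
    t = pd.Series(pseudotime).to_numpy(dtype=float)
    blocks = _sample_blocks(samples)
    rng = np.random.default_rng(seed)
    genes = sorted(expr.columns)
    X = expr[genes].to_numpy(dtype=float)

    # per-sample fixed quantities
    sample_Q: dict[str, np.ndarray] = {}
    usable_blocks: dict[str, np.ndarray] = {}
    for sid, idx in blocks.items():
        if idx.size == 0:
            logger.warning("sample %s has zero cells; skipped", sid)
            continue
        try:
            B = _design_matrix(t[idx], n_interior_knots)
        except ValueError:
            logger.warning("sample %s: unusable pseudotime; skipped", sid)
            continue
        if idx.size < B.shape[1] + 2:
            logger.warning("sample %s: too few cells for spline; skipped", sid)
            continue
        Q, _ = np.linalg.qr(B)
        sample_Q[sid] = Q
        usable_blocks[sid] = idx
    if not sample_Q:
        raise ValueError("no sample has enough cells for the spline fit")

    lr_obs = np.zeros(len(genes))
    lr_null = np.zeros((n_perm, len(genes)))
    for sid, idx in usable_blocks.items():
        Q = sample_Q[sid]
        n_s = idx.size
        Y = X[idx]                                     # n_s x genes
        Yc = Y - Y.mean(axis=0)
        rss0 = (Yc ** 2).sum(axis=0)
        proj = Q.T @ Y
        rss1 = np.maximum((Y ** 2).sum(axis=0) - (proj ** 2).sum(axis=0), 1e-300)
        lr_obs += np.where(rss0 > 0, n_s * np.log(np.maximum(rss0, 1e-300) / rss1), 0.0)
        # permutation null: per gene independent within-sample shuffles
        for g in range(len(genes)):
            col = Y[:, g]
            perms = rng.permuted(
                np.tile(np.arange(n_s), (n_perm, 1)), axis=1
            )
            Yp = col[perms].T                          # n_s x n_perm
            pr = Q.T @ Yp
            rss1p = np.maximum((col ** 2).sum() - (pr ** 2).sum(axis=0), 1e-300)
            if rss0[g] > 0:
                lr_null[:, g] += n_s * np.log(max(rss0[g], 1e-300) / rss1p)

    lr_obs = np.maximum(lr_obs, 0.0)
    lr_null = np.maximum(lr_null, 0.0)
    p = (1 + (lr_null >= lr_obs[None, :]).sum(axis=0)) / (1 + n_perm)
    fdr = bh_adjust(p)
    table = pd.DataFrame({
        "gene": genes, "lr": lr_obs, "p_value": p, "fdr": fdr,
        "dynamic": fdr < fdr_alpha,
    })

    grid = np.linspace(t.min(), t.max(), curve_grid)
    curves = mean_temporal_curves(
        expr[genes], pd.Series(pseudotime), pd.Series(samples), grid, n_interior_knots
    )
    return PseudotimeFitResult(
        table=table, curves=curves, grid=grid, n_perm=n_perm, seed=seed
    )


def mean_temporal_curves(
    expr: pd.DataFrame,
    pseudotime: pd.Series,
    samples: pd.Series,
    grid: np.ndarray,
    n_interior_knots: int = 3,
) -> pd.DataFrame:
    """Pointwise mean over samples of the per-sample fitted curves f_gs(t)
    on a common grid; returns genes x grid DataFrame."""
    t = pd.Series(pseudotime).to_numpy(dtype=float)
    blocks = _sample_blocks(samples)
    per_sample = []
    for sid, idx in blocks.items():
        try:
            B = _design_matrix(t[idx], n_interior_knots)
        except ValueError:
            continue
        if idx.size < B.shape[1] + 2:
            continue
        Y = expr.to_numpy(dtype=float)[idx]
        coefs, *_ = np.linalg.lstsq(B, Y, rcond=None)
        lo, hi = t[idx].min(), t[idx].max()
        g = np.clip(grid, lo, hi)
        qs = np.linspace(0, 1, n_interior_knots + 2)[1:-1]
        knots = np.r_[[lo] * 4, np.quantile(t[idx], qs), [hi] * 4]
        Bg = BSpline.design_matrix(
            np.clip(g, lo, hi - 1e-12 * max(1.0, abs(hi))), knots, 3
        ).toarray()
        per_sample.append(Bg @ coefs)                  # grid x genes
    if not per_sample:
        raise ValueError("no sample usable for curve fitting")
    mean_curves = np.mean(per_sample, axis=0).T        # genes x grid
    return pd.DataFrame(mean_curves, index=expr.columns, columns=np.arange(len(grid)))


def cluster_patterns(
    curves: pd.DataFrame, k: int, seed: int = 0
) -> tuple[pd.Series, np.ndarray]:
    """k-means on per-gene standardized temporal curves.

    Each curve is scaled to mean 0, SD 1 (so clustering is amplitude-
    invariant); returns (assignments indexed by gene, centroids)."""
    if k < 2:
        raise ValueError("k must be at least 2")
    if curves.shape[0] < k:
        raise ValueError("fewer curves than clusters")
    X = curves.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(Z)
    return pd.Series(labels, index=curves.index, name="pattern"), km.cluster_centers_
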