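"""Single-cell QC gates and clonotype linking.

Cell filters follow the detected-genes / mitochondrial-fraction /
ribosomal-fraction rules; gene filters remove technical and TCR-segment
genes plus genes seen in too few cells.  CD8+ T cells are gated by the
trough of the bimodal density of per-cell CD8A expression, and FEST-called
clonotypes are linked into the single-cell data by exact TRB CDR3
amino-acid match.

All operations act on an :class:`anndata.AnnData` with raw counts in
``.X`` (cells x genes) and per-cell metadata in ``.obs``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.stats import gaussian_kde

logger = logging.getLogger(__name__)

#: default symbol-prefix exclusion rules applied by :func:`filter_genes`
DEFAULT_PREFIX_EXCLUSIONS = (
    "MT-",                       # mitochondrial
    "RP-",                       # poorly supported transcript models
    "TRAV", "TRAJ", "TRAC",      # TCR segment genes (clonotype bias)
    "TRBV", "TRBD", "TRBJ", "TRBC",
    "TRDV", "TRDD", "TRDJ", "TRDC",
    "TRGV", "TRGJ", "TRGC",
)


class QcError(RuntimeError):
    pass


class UnimodalDensityError(RuntimeError):
    """The expression density has no interior trough to gate on."""


@dataclass
class QcConfig:
    min_genes: int = 250
    mad_multiplier: float = 3.0
    max_mito_frac: float = 0.10
    min_ribo_frac: float = 0.10
    min_cells_per_gene: int = 5
    prefix_exclusions: tuple[str, ...] = DEFAULT_PREFIX_EXCLUSIONS
    # extra named exclusion sets, e.g. dissociation/stress genes
    exclusion_gene_lists: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.min_genes <= 0 or self.mad_multiplier <= 0:
            raise ValueError("thresholds must be positive")
        for frac in (self.max_mito_frac, self.min_ribo_frac):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def _prefix_mask(genes: pd.Index, prefixes: tuple[str, ...]) -> np.ndarray:
    up = genes.str.upper()
    mask = np.zeros(len(genes), dtype=bool)
    for p in prefixes:
        mask |= np.asarray(up.str.startswith(p))
    return mask


def filter_cells(adata: AnnData, cfg: QcConfig | None = None) -> AnnData:
    """Remove low-quality cells.

    A cell is removed when its number of detected genes (count > 0) is
    below ``min_genes`` or above median + ``mad_multiplier`` x MAD (raw,
    unscaled MAD), when its mitochondrial count fraction exceeds
    ``max_mito_frac`` (strict), or when its ribosomal (RPL/RPS) count
    fraction is below ``min_ribo_frac`` (strict).  Per-rule removal
    counts are stored in ``.uns['qc_cell_filter']``.
    """
    cfg = cfg or QcConfig()
    X = _dense(adata.X)
    genes = pd.Index(adata.var_names)
    detected = (X > 0).sum(axis=1)
    med = np.median(detected)
    mad = np.median(np.abs(detected - med))
    upper = med + cfg.mad_multiplier * mad

    totals = X.sum(axis=1)
    totals_safe = np.where(totals > 0, totals, 1.0)
    mito = _prefix_mask(genes, ("MT-",))
    ribo = _prefix_mask(genes, ("RPL", "RPS"))
    mito_frac = X[:, mito].sum(axis=1) / totals_safe
    ribo_frac = X[:, ribo].sum(axis=1) / totals_safe

    low = detected < cfg.min_genes
    high = detected > upper
    bad_mito = mito_frac > cfg.max_mito_frac
    bad_ribo = ribo_frac < cfg.min_ribo_frac
    keep = ~(low | high | bad_mito | bad_ribo)
    report = {
        "n_input": int(adata.n_obs),
        "removed_low_genes": int(low.sum()),
        "removed_high_genes": int(high.sum()),
        "removed_mito": int(bad_mito.sum()),
        "removed_ribo": int(bad_ribo.sum()),
        "n_kept": int(keep.sum()),
        "detected_genes_upper_cut": float(upper),
    }
    logger.info("cell filter: %s", report)
    if keep.sum() == 0:
        raise QcError(f"all cells removed by QC; diagnostics: {report}")
    out = adata[keep].copy()
    out.uns["qc_cell_filter"] = report
    return out


def filter_genes(adata: AnnData, cfg: QcConfig | None = None) -> AnnData:
    """Remove excluded genes (prefix rules and named lists) and genes
    detected (count > 0) in fewer than ``min_cells_per_gene`` cells."""
    cfg = cfg or QcConfig()
    X = _dense(adata.X)
    genes = pd.Index(adata.var_names)
    excluded = _prefix_mask(genes, cfg.prefix_exclusions)
    for name, symbols in cfg.exclusion_gene_lists.items():
        hits = genes.isin(symbols)
        logger.info("gene filter: %d genes removed by list %r", hits.sum(), name)
        excluded |= hits
    n_cells = (X > 0).sum(axis=0)
    rare = n_cells < cfg.min_cells_per_gene
    keep = ~(excluded | rare)
    out = adata[:, keep].copy()
    out.uns["qc_gene_filter"] = {
        "removed_excluded": int(excluded.sum()),
        "removed_rare": int((rare & ~excluded).sum()),
        "n_kept": int(keep.sum()),
    }
    return out


def run_qc(adata: AnnData, cfg: QcConfig | None = None) -> AnnData:
    """Cells first, then genes — the documented filter order."""
    return filter_genes(filter_cells(adata, cfg), cfg)


def log_normalize(adata: AnnData, target_sum: float = 1e4) -> np.ndarray:
    """log2(library-size-normalized count + 1) — the default gate input
    when no external imputation hook is supplied."""
    X = _dense(adata.X).astype(float)
    lib = X.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    return np.log2(X / lib * target_sum + 1.0)


def gate_cd8(expr: np.ndarray, grid_size: int = 512) -> tuple[float, np.ndarray]:
    """Gate cells by the trough of a bimodal expression density.

    Fits a Gaussian-kernel density (Silverman bandwidth) on a uniform
    grid spanning the data range extended by three bandwidths, and takes
    the cutoff at the first grid point where the first derivative changes
    from negative to positive (the first interior local minimum, i.e. the
    trough between the two modes).  Returns ``(cutoff, mask)`` with
    ``mask = expr > cutoff``.

    Raises :class:`UnimodalDensityError` when no trough exists.
    """
    x = np.asarray(expr, dtype=float)
    if x.size < 100:
        raise ValueError("gate_cd8 requires at least 100 cells")
    if not np.isfinite(x).all():
        raise ValueError("expression values must be finite")
    if np.ptp(x) == 0:
        raise UnimodalDensityError("all expression values identical")
    kde = gaussian_kde(x, bw_method="silverman")
    bw = kde.factor * x.std(ddof=1)
    grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, grid_size)
    dens = kde(grid)
    sign = np.sign(np.diff(dens))
    peaks = np.where((sign[:-1] > 0) & (sign[1:] < 0))[0] + 1
    troughs = np.where((sign[:-1] < 0) & (sign[1:] > 0))[0] + 1
    # only modes carrying real mass count; tail wiggles are not bimodality
    peaks = peaks[dens[peaks] >= 0.05 * dens.max()]
    if peaks.size < 2:
        raise UnimodalDensityError("density has no interior trough (unimodal)")
    between = troughs[(troughs > peaks[0]) & (troughs < peaks[-1])]
    if between.size == 0:
        raise UnimodalDensityError("density has no interior trough (unimodal)")
    cutoff = float(grid[between[0]])
    return cutoff, x > cutoff


def link_clonotypes(
    adata: AnnData,
    calls: pd.DataFrame,
    specificity_labels: dict[str, str],
    cdr3_key: str = "trb_cdr3",
    out_key: str = "antigen_class",
) -> pd.Series:
    """Label cells by antigen class via exact TRB CDR3 amino-acid match.

    ``calls`` is a FEST call table; only verdict-true clonotypes are used.
    ``specificity_labels`` maps a clonotype's CDR3 (or its condition_id)
    to an antigen class such as "MANA", "EBV" or "InfluenzaA".  Cells
    whose CDR3 matches clonotypes of two different classes are flagged
    ``"ambiguous"``; cells without a CDR3 or without a match stay
    unlabelled (NA).  The annotation is also written to
    ``adata.obs[out_key]``.
    """
    hits = calls.loc[calls["verdict"]] if "verdict" in calls else calls
    class_of: dict[str, str] = {}
    ambiguous: set[str] = set()
    for _, row in hits.iterrows():
        cdr3 = row["cdr3_aa"]
        label = specificity_labels.get(cdr3)
        if label is None and "condition_id" in row:
            label = specificity_labels.get(row["condition_id"])
        if label is None:
            continue
        if cdr3 in class_of and class_of[cdr3] != label:
            ambiguous.add(cdr3)
        class_of[cdr3] = label
    cell_cdr3 = adata.obs.get(cdr3_key)
    if cell_cdr3 is None:
        raise KeyError(f"adata.obs lacks {cdr3_key!r}")
    labels = cell_cdr3.map(
        lambda c: "ambiguous" if c in ambiguous else class_of.get(c)
        if isinstance(c, str) else None
    )
    labels = pd.Series(labels, index=adata.obs_names, name=out_key, dtype=object)
    adata.obs[out_key] = labels
    return labels
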