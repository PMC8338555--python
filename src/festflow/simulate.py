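"""Synthetic-data generators with known ground truth.

Three generators cover the pipeline's inputs:

* :func:`simulate_repertoire` — multi-condition peptide-stimulation
  TCR-seq experiments with replicate wells and spiked antigen-driven
  clonal expansions;
* :func:`simulate_sc` — single-cell count matrices (Poisson-lognormal)
  with cluster structure, binary covariates, batch effects, power-law
  clonotype sizes with grammar-valid CDR3s, and antigen-labelled clones
  enriched in designated clusters;
* :func:`simulate_pseudotime` — per-sample pseudotime with genes of
  known dynamic template.

Every generator is seed-deterministic and returns a truth record
sufficient to score the downstream module without external data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData

from .repertoire import ClonotypeTable

logger = logging.getLogger(__name__)

_AA = "ARNDCQEGHILKMFPSTWYV"


def _random_cdr3(rng: np.random.Generator, min_len: int = 9, max_len: int = 17) -> str:
    """Grammar-valid CDR3: starts with C, ends with F or W, length >= 7."""
    length = int(rng.integers(min_len, max_len + 1))
    middle = "".join(rng.choice(list(_AA), size=length - 2))
    return "C" + middle + ("F" if rng.random() < 0.8 else "W")


def _clone_pool(rng: np.random.Generator, n: int) -> tuple[list[str], list[str]]:
    cdr3s: list[str] = []
    seen: set[str] = set()
    while len(cdr3s) < n:
        c = _random_cdr3(rng)
        if c not in seen:
            seen.add(c)
            cdr3s.append(c)
    v_genes = [f"TRBV{int(rng.integers(2, 31))}" for _ in range(n)]
    return cdr3s, v_genes


@dataclass
class RepertoireSimConfig:
    """Stimulation-experiment generator settings.

    Defaults emulate a MANAFEST-scale assay: a few hundred clonotypes per
    culture, 1e5 productive reads per condition split over 10 wells, and
    spiked clones expanded 20-fold in their target condition.
    """

    n_clones: int = 200
    dirichlet_alpha: float = 1.0
    depth: int = 100_000
    n_wells: int = 10
    conditions: tuple[str, ...] = ("peptide_A", "peptide_B", "peptide_C")
    control_id: str = "no_peptide"
    # (clone index, target condition, fold expansion)
    spiked_clones: tuple[tuple[int, str, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0 or self.n_clones <= 1 or self.n_wells < 1:
            raise ValueError("invalid repertoire sim config")
        for idx, cond, fold in self.spiked_clones:
            if fold <= 1:
                raise ValueError("spike folds must exceed 1")
            if not 0 <= idx < self.n_clones:
                raise ValueError("spiked clone index out of range")
            if cond not in self.conditions:
                raise ValueError(f"spike target {cond!r} not a condition")


def simulate_repertoire(
    config: RepertoireSimConfig,
) -> tuple[dict[str, ClonotypeTable], ClonotypeTable, pd.DataFrame]:
    """Simulate condition tables, a no-peptide control and the spike truth.

    Baseline clone frequencies are drawn once from a symmetric Dirichlet;
    in each spiked condition the target clones' frequencies are multiplied
    by their fold and renormalized.  Reads are multinomial per well (the
    condition depth split evenly across wells, remainder to the first
    wells), so total reads per condition equal ``depth`` exactly.

    Returns ``(condition_tables, control_table, truth)`` where truth has
    columns ``cdr3_aa, condition_id, fold``.
    """
    rng = np.random.default_rng(config.seed)
    cdr3s, v_genes = _clone_pool(rng, config.n_clones)
    base = rng.dirichlet(np.full(config.n_clones, config.dirichlet_alpha))
    if base.min() * config.depth < 0.1:
        warnings.warn("depth may be too low to represent the rarest clones",
                      stacklevel=2)

    spikes_by_cond: dict[str, list[tuple[int, float]]] = {}
    for idx, cond, fold in config.spiked_clones:
        spikes_by_cond.setdefault(cond, []).append((idx, fold))

    def make_table(cid: str, freqs: np.ndarray) -> ClonotypeTable:
        per_well = np.full(config.n_wells, config.depth // config.n_wells)
        per_well[: config.depth % config.n_wells] += 1
        frames = []
        for w, n_reads in enumerate(per_well):
            counts = rng.multinomial(n_reads, freqs)
            nz = counts > 0
            frames.append(pd.DataFrame({
                "cdr3_aa": np.array(cdr3s)[nz],
                "v_gene": np.array(v_genes)[nz],
                "reads": counts[nz],
                "productive": True,
                "well_id": f"{cid}_w{w + 1}",
            }))
        return ClonotypeTable(
            condition_id=cid,
            records=pd.concat(frames, ignore_index=True),
            well_ids=[f"{cid}_w{w + 1}" for w in range(config.n_wells)],
        )

    tables: dict[str, ClonotypeTable] = {}
    truth_rows = []
    for cid in config.conditions:
        freqs = base.copy()
        for idx, fold in spikes_by_cond.get(cid, []):
            freqs[idx] *= fold
            truth_rows.append({"cdr3_aa": cdr3s[idx], "condition_id": cid, "fold": fold})
        freqs = freqs / freqs.sum()
        tables[cid] = make_table(cid, freqs)
    control = make_table(config.control_id, base)
    truth = pd.DataFrame(truth_rows, columns=["cdr3_aa", "condition_id", "fold"])
    return tables, control, truth


@dataclass
class ScSimConfig:
    """Single-cell generator settings.

    Counts follow a Poisson-lognormal model around per-cluster gene
    means, with optional covariate (MPR/non-MPR) shifts on a designated
    gene subset, multiplicative batch effects and dropout.  A fraction of
    cells carries a TRB CDR3 from a power-law clone-size distribution;
    antigen-labelled clones are placed preferentially in designated
    clusters at a configurable enrichment.
    """

    n_cells: int = 2000
    n_genes: int = 1000
    n_clusters: int = 4
    n_samples: int = 4
    cluster_logmean_sd: float = 0.8
    base_logmean: float = -0.5
    covariate_effect: float = 1.0
    n_covariate_genes: int = 20
    batch_effect_sd: float = 0.1
    noise_sd: float = 0.3
    dropout: float = 0.3
    n_clones: int = 60
    clone_power: float = 1.5
    vdj_fraction: float = 0.6
    n_labelled_clones: int = 5
    labelled_clusters: tuple[int, ...] = (0,)
    labelled_enrichment: float = 5.0
    antigen_class: str = "MANA"
    cd8_gene: bool = True
    cd8_pos_fraction: float = 0.6
    seed: int = 0


def simulate_sc(config: ScSimConfig) -> tuple[AnnData, dict]:
    """Simulate a CellDataset (AnnData) plus a ground-truth record.

    Truth keys: ``clusters`` (per-cell), ``de_genes`` (covariate-shifted
    genes), ``clone_classes`` (cdr3 -> antigen class), ``labelled_clusters``,
    ``cd8_truth`` (per-cell boolean, when cd8_gene).
    """
    rng = np.random.default_rng(config.seed)
    # housekeeping genes so the mito/ribo QC fractions are exercised
    mito_genes = ["MT-ND1", "MT-ND2", "MT-CO1"]
    ribo_genes = ["RPL03", "RPL05", "RPL10", "RPL13", "RPS03", "RPS05", "RPS10", "RPS18"]
    special = (["CD8A"] if config.cd8_gene else []) + mito_genes + ribo_genes
    n_regular = config.n_genes - len(special)
    genes = special + [f"G{i + 1:04d}" for i in range(n_regular)]

    clusters = rng.integers(0, config.n_clusters, size=config.n_cells)
    samples = np.array([f"S{i % config.n_samples + 1}" for i in range(config.n_cells)])
    rng.shuffle(samples)
    batches = np.where(pd.Series(samples).str[1:].astype(int) % 2 == 0, "b2", "b1")
    group = np.where(pd.Series(samples).str[1:].astype(int) <= config.n_samples // 2,
                     "MPR", "non-MPR")

    # cluster-specific log means
    logmeans = config.base_logmean + rng.normal(
        0, config.cluster_logmean_sd, size=(config.n_clusters, len(genes))
    )
    regular = [g for g in genes if g not in special]
    de_genes = list(rng.choice(regular, size=config.n_covariate_genes, replace=False))
    de_idx = [genes.index(g) for g in de_genes]

    mu = logmeans[clusters]
    mu[np.isin(group, ["MPR"])[:, None] & np.isin(
        np.arange(len(genes)), de_idx)[None, :]] += config.covariate_effect
    batch_shift = {b: rng.normal(0, config.batch_effect_sd, size=len(genes))
                   for b in np.unique(batches)}
    mu = mu + np.stack([batch_shift[b] for b in batches])

    # housekeeping means: high ribosomal load, modest mitochondrial load
    for g in mito_genes:
        mu[:, genes.index(g)] = 1.0
    for g in ribo_genes:
        mu[:, genes.index(g)] = 3.3

    # CD8A bimodal across a CD8+/CD8- split, independent of clusters
    cd8_truth = None
    if config.cd8_gene:
        cd8_truth = rng.random(config.n_cells) < config.cd8_pos_fraction
        mu[:, 0] = np.where(cd8_truth, 2.0, -2.0)

    lam = np.exp(mu + rng.normal(0, config.noise_sd, size=mu.shape))
    counts = rng.poisson(lam)
    drop = rng.random(counts.shape) < config.dropout
    if config.cd8_gene:
        drop[:, 0] = False  # CD8A emulates imputed input: bimodality preserved
    counts[drop] = 0

    # clonotypes: power-law sizes, labelled clones pushed into target clusters
    cdr3s, _ = _clone_pool(rng, config.n_clones)
    weights = 1.0 / np.arange(1, config.n_clones + 1) ** config.clone_power
    weights /= weights.sum()
    has_vdj = rng.random(config.n_cells) < config.vdj_fraction
    clone_idx = rng.choice(config.n_clones, size=config.n_cells, p=weights)
    labelled_clones = list(range(config.n_labelled_clones))
    # enrich labelled clones in target clusters by preferential reassignment
    in_target = np.isin(clusters, config.labelled_clusters)
    is_labelled_clone = np.isin(clone_idx, labelled_clones)
    flip = is_labelled_clone & ~in_target & (
        rng.random(config.n_cells) < 1 - 1 / config.labelled_enrichment
    )
    clone_idx = clone_idx.copy()
    clone_idx[flip] = rng.choice(
        [i for i in range(config.n_clones) if i not in labelled_clones], size=flip.sum()
    )
    trb = np.array([cdr3s[i] for i in clone_idx], dtype=object)
    trb[~has_vdj] = None

    obs = pd.DataFrame({
        "sample": samples,
        "batch": batches,
        "response": group,
        "cluster": pd.Categorical([f"c{c}" for c in clusters]),
        "trb_cdr3": trb,
    }, index=[f"cell{i + 1:05d}" for i in range(config.n_cells)])
    adata = AnnData(
        X=counts.astype(np.int64),
        obs=obs,
        var=pd.DataFrame(index=genes),
    )
    truth = {
        "clusters": pd.Series([f"c{c}" for c in clusters], index=obs.index),
        "de_genes": de_genes,
        "clone_classes": {cdr3s[i]: config.antigen_class for i in labelled_clones},
        "labelled_clusters": [f"c{c}" for c in config.labelled_clusters],
        "cd8_truth": None if cd8_truth is None else pd.Series(cd8_truth, index=obs.index),
    }
    return adata, truth


#: canonical dynamic templates on [0, 1]
TEMPLATES = {
    "rising": lambda t: t,
    "falling": lambda t: 1.0 - t,
    "transient": lambda t: np.exp(-((t - 0.5) ** 2) / (2 * 0.15 ** 2)),
    "flat": lambda t: np.zeros_like(t),
}


def simulate_pseudotime(
    n_cells: int = 300,
    n_samples: int = 3,
    n_dynamic: int = 30,
    n_flat: int = 70,
    templates: tuple[str, ...] = ("rising", "falling", "transient"),
    amplitude: float = 1.0,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series, dict]:
    """Simulate pseudotime expression with known dynamic genes.

    Returns ``(expr, pseudotime, samples, truth)``; expr is cells x genes
    (dynamic genes named ``dyn_<template>_<i>``, flat genes ``flat_<i>``),
    pseudotime uniform per sample, and truth maps gene -> template name.
    """
    rng = np.random.default_rng(seed)
    t = rng.uniform(0, 1, size=n_cells)
    samples = pd.Series(
        [f"S{i % n_samples + 1}" for i in range(n_cells)], name="sample"
    )
    cols = {}
    truth: dict[str, str] = {}
    for i in range(n_dynamic):
        name = templates[i % len(templates)]
        gene = f"dyn_{name}_{i + 1:03d}"
        cols[gene] = amplitude * TEMPLATES[name](t) + rng.normal(0, noise_sd, n_cells)
        truth[gene] = name
    for i in range(n_flat):
        gene = f"flat_{i + 1:03d}"
        cols[gene] = 0.5 + rng.normal(0, noise_sd, n_cells)
        truth[gene] = "flat"
    expr = pd.DataFrame(cols, index=[f"cell{i + 1:05d}" for i in range(n_cells)])
    pseudotime = pd.Series(t, index=expr.index, name="pseudotime")
    samples.index = expr.index
    return expr, pseudotime, samples, {"templates": truth}
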