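"""FEST caller: antigen-specific clonotype calling from peptide-stimulated
cultures versus a no-peptide control.

A clonotype is called antigen-specific for a peptide condition when all
four criteria hold:

1. significant expansion versus the no-peptide control
   (one-sided Fisher exact test, Benjamini-Hochberg FDR < alpha);
2. significant expansion versus every other peptide-stimulated culture
   (FDR < alpha), except cultures stimulated with related peptides derived
   from the same mutation;
3. odds ratio > ``or_threshold`` versus the no-peptide control;
4. present in at least ``min_well_fraction`` of the culture wells.

Only clonotypes reaching ``read_floor`` reads in the stimulated condition
are eligible (the floor guards against PCR noise; 300 for FTIC-sequenced
assays, 30 for Adaptive-sequenced assays).  Assays testing few peptides
are run in triplicate instead; see :func:`call_triplicate_mode`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .repertoire import ClonotypeTable

logger = logging.getLogger(__name__)


class FestConfigError(ValueError):
    pass


@dataclass
class FestConfig:
    """Thresholds for the four calling criteria."""

    fdr_alpha: float = 0.05
    or_threshold: float = 5.0
    min_well_fraction: float = 0.10
    read_floor: int = 300  # 300 for FTIC, 30 for Adaptive provider
    triplicate_mode: bool = False
    # conditions sharing a mutation are exempt from mutual comparison
    mutation_groups: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.fdr_alpha < 1:
            raise FestConfigError("fdr_alpha must be in (0, 1)")
        if self.or_threshold <= 0:
            raise FestConfigError("or_threshold must be positive")
        if not 0 <= self.min_well_fraction <= 1:
            raise FestConfigError("min_well_fraction must be in [0, 1]")


def fisher_expansion_test(a: int, n1: int, b: int, n2: int) -> tuple[float, float]:
    """One-sided (greater) Fisher exact test for clonal expansion.

    Tests whether a clone with ``a`` of ``n1`` reads in the stimulated
    condition is expanded relative to ``b`` of ``n2`` reads in the
    reference, i.e. the upper tail of the hypergeometric distribution of
    ``a`` given the margins of ``[[a, n1-a], [b, n2-b]]``.

    Returns ``(p, odds_ratio)``; the odds ratio uses a Haldane-Anscombe
    +0.5 correction on all four cells when any cell is zero.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("totals n1 and n2 must be positive")
    if not (0 <= a <= n1 and 0 <= b <= n2):
        raise ValueError("clone reads must lie within totals")
    p = float(hypergeom.sf(a - 1, n1 + n2, a + b, n1))
    cells = np.array([a, n1 - a, b, n2 - b], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    odds_ratio = (cells[0] * cells[3]) / (cells[1] * cells[2])
    return min(p, 1.0), float(odds_ratio)


def _fisher_p_vec(a: np.ndarray, n1: int, b: np.ndarray, n2: int) -> np.ndarray:
    """Vectorized one-sided expansion p-values for many clones sharing margins."""
    return np.minimum(hypergeom.sf(a - 1, n1 + n2, a + b, n1), 1.0)


def _odds_ratio_vec(a: np.ndarray, n1: int, b: np.ndarray, n2: int) -> np.ndarray:
    cells = np.stack([a, n1 - a, b, n2 - b]).astype(float)
    zero = (cells == 0).any(axis=0)
    cells[:, zero] += 0.5
    return (cells[0] * cells[3]) / (cells[1] * cells[2])


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def well_presence_fraction(cdr3: str, table: ClonotypeTable) -> float:
    """Fraction of the condition's wells in which the clonotype has >= 1 read."""
    if table.n_wells == 0:
        raise ValueError(f"{table.condition_id}: table has no wells")
    rec = table.records
    present = rec.loc[(rec["cdr3_aa"] == cdr3) & (rec["reads"] > 0), "well_id"]
    return present.nunique() / table.n_wells


def _comparison_frame(
    cond: ClonotypeTable, ref_counts: pd.Series, ref_total: int, eligible: pd.Index
) -> pd.DataFrame:
    """p-values and ORs of `cond`'s eligible clonotypes versus a reference pool."""
    counts = cond.condition_counts()
    n1 = int(counts.sum())
    a = counts.reindex(eligible, fill_value=0).to_numpy()
    b = ref_counts.reindex(eligible, fill_value=0).to_numpy()
    p = _fisher_p_vec(a, n1, b, ref_total)
    orr = _odds_ratio_vec(a, n1, b, ref_total)
    return pd.DataFrame(
        {"reads_condition": a, "reads_ref": b, "p": p, "odds_ratio": orr},
        index=eligible,
    )


def call_antigen_specific(
    condition_tables: Sequence[ClonotypeTable],
    control_table: ClonotypeTable | None,
    config: FestConfig | None = None,
) -> pd.DataFrame:
    """Run the four-criterion FEST caller.

    Returns one row per eligible (clonotype, condition) with columns
    ``cdr3_aa, condition_id, reads_condition, reads_control, p_vs_control,
    fdr_vs_control, max_fdr_vs_others, odds_ratio, well_fraction,
    crit_control, crit_others, crit_or, crit_wells, verdict``.

    FDR adjustment is applied within each pairwise comparison family
    (condition vs control, and condition vs each other condition) across
    all eligible clonotypes in that family.  Conditions sharing a
    ``mutation_groups`` entry are exempt from mutual comparison.
    """
    config = config or FestConfig()
    if control_table is None:
        raise FestConfigError("a no-peptide control table is required")
    if not condition_tables:
        raise FestConfigError("at least one peptide condition is required")

    control_counts = control_table.condition_counts()
    control_total = int(control_counts.sum())
    cond_by_id = {t.condition_id: t for t in sorted(condition_tables, key=lambda t: t.condition_id)}

    rows: list[pd.DataFrame] = []
    for cid, cond in cond_by_id.items():
        counts = cond.condition_counts()
        eligible = counts.index[counts >= config.read_floor]
        if eligible.empty:
            continue
        vs_ctrl = _comparison_frame(cond, control_counts, control_total, eligible)
        vs_ctrl["fdr"] = bh_adjust(vs_ctrl["p"].to_numpy())

        # criterion 2: expansion vs every other (unrelated) peptide condition
        group = config.mutation_groups.get(cid)
        max_fdr_others = pd.Series(0.0, index=eligible)
        for oid, other in cond_by_id.items():
            if oid == cid:
                continue
            if group is not None and config.mutation_groups.get(oid) == group:
                continue
            other_counts = other.condition_counts()
            frame = _comparison_frame(cond, other_counts, int(other_counts.sum()), eligible)
            fdr = bh_adjust(frame["p"].to_numpy())
            max_fdr_others = np.maximum(max_fdr_others, pd.Series(fdr, index=eligible))

        well_frac = pd.Series(
            [well_presence_fraction(c, cond) for c in eligible], index=eligible
        )
        crit1 = vs_ctrl["fdr"] < config.fdr_alpha
        crit2 = max_fdr_others < config.fdr_alpha
        crit3 = vs_ctrl["odds_ratio"] > config.or_threshold
        crit4 = well_frac >= config.min_well_fraction
        rows.append(
            pd.DataFrame(
                {
                    "cdr3_aa": eligible,
                    "condition_id": cid,
                    "reads_condition": vs_ctrl["reads_condition"].to_numpy(),
                    "reads_control": vs_ctrl["reads_ref"].to_numpy(),
                    "p_vs_control": vs_ctrl["p"].to_numpy(),
                    "fdr_vs_control": vs_ctrl["fdr"].to_numpy(),
                    "max_fdr_vs_others": max_fdr_others.to_numpy(),
                    "odds_ratio": vs_ctrl["odds_ratio"].to_numpy(),
                    "well_fraction": well_frac.to_numpy(),
                    "crit_control": crit1.to_numpy(),
                    "crit_others": crit2.to_numpy(),
                    "crit_or": crit3.to_numpy(),
                    "crit_wells": crit4.to_numpy(),
                }
            )
        )
    if not rows:
        return _empty_calls()
    calls = pd.concat(rows, ignore_index=True)
    calls["verdict"] = (
        calls["crit_control"] & calls["crit_others"] & calls["crit_or"] & calls["crit_wells"]
    )
    return calls.sort_values(["condition_id", "cdr3_aa"], ignore_index=True)


def _empty_calls() -> pd.DataFrame:
    cols = [
        "cdr3_aa", "condition_id", "reads_condition", "reads_control",
        "p_vs_control", "fdr_vs_control", "max_fdr_vs_others", "odds_ratio",
        "well_fraction", "crit_control", "crit_others", "crit_or", "crit_wells",
        "verdict",
    ]
    return pd.DataFrame(columns=cols)


def call_triplicate_mode(
    condition_tables: Sequence[ClonotypeTable],
    control_table: ClonotypeTable | None,
    config: FestConfig | None = None,
    allow_non_triplicate: bool = False,
) -> pd.DataFrame:
    """Triplicate-culture caller for assays testing few peptides.

    Each condition's wells are treated as independent replicate cultures,
    each tested against the no-peptide control (FDR within each replicate
    across its eligible clonotypes).  A clonotype is reactive for a
    condition when it is significantly expanded (FDR < alpha) in at least
    2 of the 3 replicates and not significantly expanded in any replicate
    of any other condition.
    """
    config = config or FestConfig(triplicate_mode=True)
    if not config.triplicate_mode:
        raise FestConfigError("call_triplicate_mode requires triplicate_mode=True")
    if control_table is None:
        raise FestConfigError("a no-peptide control table is required")
    for t in condition_tables:
        if t.n_wells != 3 and not allow_non_triplicate:
            raise FestConfigError(
                f"{t.condition_id}: expected 3 replicate wells, found {t.n_wells} "
                "(pass allow_non_triplicate=True to override)"
            )

    control_counts = control_table.condition_counts()
    control_total = int(control_counts.sum())

    # per (condition, replicate well): significance of each eligible clone
    sig: dict[tuple[str, str], pd.Series] = {}
    eligible_by_cond: dict[str, pd.Index] = {}
    for cond in condition_tables:
        counts = cond.condition_counts()
        eligible_by_cond[cond.condition_id] = counts.index[counts >= config.read_floor]
        for well in cond.well_ids:
            rec = cond.records
            wc = rec.loc[rec["well_id"] == well].groupby("cdr3_aa")["reads"].sum()
            n1 = int(wc.sum())
            if n1 == 0:
                continue
            clones = wc.index
            p = _fisher_p_vec(
                wc.to_numpy(), n1,
                control_counts.reindex(clones, fill_value=0).to_numpy(), control_total,
            )
            fdr = bh_adjust(p)
            sig[(cond.condition_id, well)] = pd.Series(fdr < config.fdr_alpha, index=clones)

    rows = []
    for cond in condition_tables:
        cid = cond.condition_id
        for clone in eligible_by_cond[cid]:
            n_sig = sum(
                bool(sig.get((cid, w), pd.Series(dtype=bool)).get(clone, False))
                for w in cond.well_ids
            )
            sig_elsewhere = any(
                bool(s.get(clone, False))
                for (ocid, _), s in sig.items()
                if ocid != cid
            )
            rows.append(
                {
                    "cdr3_aa": clone,
                    "condition_id": cid,
                    "n_replicates_significant": n_sig,
                    "significant_elsewhere": sig_elsewhere,
                    "verdict": n_sig >= 2 and not sig_elsewhere,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["cdr3_aa", "condition_id", "n_replicates_significant",
                 "significant_elsewhere", "verdict"],
    ).sort_values(["condition_id", "cdr3_aa"], ignore_index=True)
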