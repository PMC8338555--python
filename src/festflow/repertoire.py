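"""Reading, validation and preprocessing of clonotype tables from
peptide-stimulated T-cell cultures (TCR-seq).

A *clonotype table* holds per-well read counts for TRB CDR3 amino-acid
clonotypes observed in one culture condition (a peptide, a peptide pool,
or the no-peptide control).  Preprocessing retains productive
rearrangements with a grammatically valid CDR3 (starts with C, ends with
F or W, length >= 7) and aggregates duplicate CDR3s within a well;
whole samples with fewer than 1,000 productive reads are excluded from
downstream testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: canonical column names used internally
REQUIRED_COLUMNS = ("cdr3_aa", "v_gene", "reads", "productive")

#: built-in column dialects (header-name -> canonical-name mappings)
DIALECTS: dict[str, dict[str, str]] = {
    "generic": {
        "cdr3_aa": "cdr3_aa",
        "v_gene": "v_gene",
        "reads": "reads",
        "productive": "productive",
        "well_id": "well_id",
    },
    # AIRR Rearrangement TSV style
    "airr": {
        "junction_aa": "cdr3_aa",
        "v_call": "v_gene",
        "duplicate_count": "reads",
        "productive": "productive",
        "well_id": "well_id",
    },
    # Adaptive immunoSEQ-style export
    "adaptive": {
        "aminoAcid": "cdr3_aa",
        "vGeneName": "v_gene",
        "count (templates/reads)": "reads",
        "sequenceStatus": "productive",
        "well_id": "well_id",
    },
}

_TRUE_STRINGS = {"true", "t", "1", "yes", "y", "in", "productive"}


class ClonotypeFormatError(ValueError):
    """Raised when a clonotype file cannot be parsed."""


@dataclass
class ClonotypeTable:
    """Per-condition clonotype read counts with replicate-well provenance.

    ``records`` is a DataFrame with columns ``cdr3_aa, v_gene, reads,
    productive, well_id``; one row per (well, clonotype) observation.
    """

    condition_id: str
    records: pd.DataFrame
    well_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.records.columns]
        if missing:
            raise ClonotypeFormatError(
                f"{self.condition_id}: missing required columns {missing}"
            )
        if "well_id" not in self.records.columns:
            self.records = self.records.assign(well_id=f"{self.condition_id}_w1")
        if not self.well_ids:
            self.well_ids = sorted(self.records["well_id"].astype(str).unique())
        if (self.records["reads"] < 0).any():
            raise ClonotypeFormatError(f"{self.condition_id}: negative read counts")

    @property
    def n_wells(self) -> int:
        return len(self.well_ids)

    @property
    def total_productive_reads(self) -> int:
        rec = self.records
        return int(rec.loc[rec["productive"], "reads"].sum())

    def condition_counts(self) -> pd.Series:
        """Clonotype read counts aggregated over wells (index: cdr3_aa)."""
        return self.records.groupby("cdr3_aa")["reads"].sum().sort_index()

    def copy(self) -> "ClonotypeTable":
        return ClonotypeTable(
            condition_id=self.condition_id,
            records=self.records.copy(),
            well_ids=list(self.well_ids),
        )


def _coerce_productive(col: pd.Series) -> pd.Series:
    if col.dtype == bool:
        return col
    return col.astype(str).str.strip().str.lower().isin(_TRUE_STRINGS)


def load_dialect(spec: str | Path | Mapping[str, str]) -> dict[str, str]:
    """Resolve a dialect given a built-in name, a YAML/JSON file path, or a mapping."""
    if isinstance(spec, Mapping):
        return dict(spec)
    if str(spec) in DIALECTS:
        return dict(DIALECTS[str(spec)])
    path = Path(spec)
    if path.exists():
        with open(path) as fh:
            mapping = yaml.safe_load(fh)
        if not isinstance(mapping, dict):
            raise ClonotypeFormatError(f"dialect file {path} must map column names")
        return {str(k): str(v) for k, v in mapping.items()}
    raise ClonotypeFormatError(f"unknown dialect {spec!r}")


def read_clonotype_table(
    path: str | Path,
    dialect: str | Path | Mapping[str, str] = "generic",
    condition_id: str | None = None,
) -> ClonotypeTable:
    """Read a tab-separated clonotype file into a :class:`ClonotypeTable`.

    ``dialect`` maps file header names to the canonical columns
    ``cdr3_aa/v_gene/reads/productive`` (and optionally ``well_id``).
    Rows with an unparseable read count are dropped and counted in the log.
    """
    path = Path(path)
    mapping = load_dialect(dialect)
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ClonotypeFormatError(f"{path}: empty file") from exc
    if raw.empty:
        raise ClonotypeFormatError(f"{path}: no data rows")
    renamed = raw.rename(columns={k: v for k, v in mapping.items() if k in raw.columns})
    missing = [c for c in REQUIRED_COLUMNS if c not in renamed.columns]
    if missing:
        raise ClonotypeFormatError(
            f"{path}: required columns {missing} not resolvable via dialect"
        )
    keep = [c for c in (*REQUIRED_COLUMNS, "well_id") if c in renamed.columns]
    df = renamed[keep].copy()
    n_before = len(df)
    df["reads"] = pd.to_numeric(df["reads"], errors="coerce")
    df = df.dropna(subset=["reads", "cdr3_aa"])
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.warning("%s: dropped %d unparseable rows", path, n_dropped)
    df["reads"] = df["reads"].astype(int)
    df["productive"] = _coerce_productive(df["productive"])
    df["cdr3_aa"] = df["cdr3_aa"].astype(str)
    return ClonotypeTable(condition_id=condition_id or path.stem, records=df.reset_index(drop=True))


def write_clonotype_table(table: ClonotypeTable, path: str | Path) -> None:
    """Write a table as generic-dialect TSV (round-trips with the generic reader)."""
    cols = ["cdr3_aa", "v_gene", "reads", "productive", "well_id"]
    table.records[cols].to_csv(path, sep="\t", index=False)


def cdr3_is_valid(cdr3: str) -> bool:
    """Grammar check: starts with C, ends with F or W, length >= 7."""
    s = cdr3.upper()
    return len(s) >= 7 and s.startswith("C") and s[-1] in "FW"


def preprocess_cdr3(table: ClonotypeTable) -> ClonotypeTable:
    """Apply the CDR3 retention rules and aggregate duplicates within wells.

    Retains productive records whose (uppercased) CDR3 starts with C, ends
    with F or W and is at least 7 residues long; records sharing a CDR3
    within a well are summed.  Idempotent.
    """
    rec = table.records.copy()
    rec["cdr3_aa"] = rec["cdr3_aa"].str.upper()
    ok = rec["productive"] & rec["cdr3_aa"].map(cdr3_is_valid)
    n_removed = int((~ok).sum())
    if n_removed:
        logger.info("%s: removed %d records failing CDR3/productive rules",
                    table.condition_id, n_removed)
    rec = rec[ok]
    agg = (
        rec.groupby(["well_id", "cdr3_aa"], as_index=False)
        .agg(reads=("reads", "sum"), v_gene=("v_gene", "first"))
        .assign(productive=True)
    )
    agg = agg[["cdr3_aa", "v_gene", "reads", "productive", "well_id"]]
    return ClonotypeTable(
        condition_id=table.condition_id,
        records=agg.reset_index(drop=True),
        well_ids=list(table.well_ids),
    )


def exclude_low_depth(
    tables: Sequence[ClonotypeTable], min_reads: int = 1000
) -> tuple[list[ClonotypeTable], list[ClonotypeTable]]:
    """Split tables into (kept, excluded) by total productive reads.

    Samples with *fewer than* ``min_reads`` productive reads are excluded
    (the comparison is strict, so a sample at exactly the threshold is kept).
    """
    kept: list[ClonotypeTable] = []
    excluded: list[ClonotypeTable] = []
    for t in tables:
        if t.total_productive_reads < min_reads:
            logger.warning(
                "excluding %s: %d productive reads < %d",
                t.condition_id, t.total_productive_reads, min_reads,
            )
            excluded.append(t)
        else:
            kept.append(t)
    return kept, excluded
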