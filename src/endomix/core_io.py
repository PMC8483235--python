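"""Reading, writing and normalising genus abundance tables and sample metadata.

The substrate of every downstream stage is a samples x genera abundance
matrix (counts or relative abundances) plus a longitudinal metadata table
carrying, per sputum sample: patient id, visit ordering, stable/exacerbation
status, sputum differential cell percentages, optional log-scale mediator
measurements and demographic covariates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenusAbundanceTable",
    "SampleMetadata",
    "CohortDataset",
    "RAREFACTION_PRESETS",
    "load_cohort",
    "load_abundance_tsv",
    "load_biom_table",
    "load_metadata_tsv",
    "to_relative",
    "rarefy",
    "save_cohort",
]

#: Rarefaction depths used for the discovery (MiSeq V4) and validation
#: (454 V3–V5) cohort emulations. Never applied silently.
RAREFACTION_PRESETS = {"discovery": 29_117, "validation": 2_207}

REQUIRED_METADATA_COLUMNS = ("sample_id", "patient_id", "visit_index", "day_offset", "visit_type")

CELL_COLUMNS = (
    "neutrophil_pct",
    "eosinophil_pct",
    "lymphocyte_pct",
    "macrophage_pct",
    "epithelial_pct",
)

VISIT_TYPES = ("stable", "exacerbation")


@dataclass
class GenusAbundanceTable:
    """Samples x genera abundance matrix.

    Parameters
    ----------
    data:
        DataFrame indexed by sample id with one column per genus. Values are
        non-negative and contain no missing entries.
    kind:
        ``"counts"`` (integer read counts) or ``"relative"`` (rows sum to 1).
    """

    data: pd.DataFrame
    kind: str = "counts"

    def __post_init__(self) -> None:
        self.validate()

    # -- contracts -----------------------------------------------------
    def validate(self) -> None:
        if self.kind not in ("counts", "relative"):
            raise ValueError(f"kind must be 'counts' or 'relative', got {self.kind!r}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate genus names: {dups}")
        values = self.data.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValueError("abundance table contains missing values")
        if (values < 0).any():
            raise ValueError("abundance table contains negative values")
        if self.kind == "relative":
            sums = values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-6):
                bad = self.data.index[np.abs(sums - 1.0) > 1e-6].tolist()
                raise ValueError(f"relative abundance rows do not sum to 1: {bad[:5]}")

    # -- convenience ---------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def genus_names(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def to_relative(self) -> "GenusAbundanceTable":
        return to_relative(self)


@dataclass
class SampleMetadata:
    """Per-sample longitudinal clinical context.

    ``data`` is indexed by sample id and carries at least patient_id,
    visit_index (1-based), day_offset (days since patient baseline) and
    visit_type (stable / exacerbation). Sputum differential cell
    percentages (``*_pct``), mediator columns (``mediator_*``, log scale)
    and covariates (age, sex, bmi, smoking, ics, season, site) are optional;
    missing cell percentages propagate downstream as an unassigned endotype.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_METADATA_COLUMNS[1:] if c not in df.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids in metadata: {dups}")
        bad_types = set(df["visit_type"].unique()) - set(VISIT_TYPES)
        if bad_types:
            raise ValueError(f"unknown visit_type values: {sorted(bad_types)}")
        for col in CELL_COLUMNS:
            if col in df.columns:
                vals = df[col].dropna()
                if ((vals < 0) | (vals > 100)).any():
                    raise ValueError(f"{col} outside [0, 100]")
        # visit_index strictly increasing with day_offset within patient
        for pid, grp in df.groupby("patient_id"):
            ordered = grp.sort_values("visit_index")
            if not ordered["day_offset"].is_monotonic_increasing:
                raise ValueError(
                    f"patient {pid}: day_offset not increasing with visit_index"
                )

    @property
    def sample_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def mediator_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith("mediator_")]


@dataclass
class CohortDataset:
    """Validated abundance table + metadata with conserved bookkeeping."""

    table: GenusAbundanceTable
    metadata: SampleMetadata
    bookkeeping: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        table_ids = set(self.table.sample_ids)
        meta_ids = set(self.metadata.sample_ids)
        missing = sorted(table_ids - meta_ids)
        if missing:
            raise ValueError(f"samples absent from metadata: {missing}")
        if not self.bookkeeping:
            self.bookkeeping = self.recompute_bookkeeping()
        self.check_conservation()

    def recompute_bookkeeping(self) -> dict:
        meta = self.metadata.data.loc[self.table.sample_ids]
        by_type = meta["visit_type"].value_counts().to_dict()
        return {
            "n_samples": int(self.table.n_samples),
            "n_patients": int(meta["patient_id"].nunique()),
            "per_visit_type": {k: int(by_type.get(k, 0)) for k in VISIT_TYPES},
        }

    def check_conservation(self) -> None:
        fresh = self.recompute_bookkeeping()
        if fresh != self.bookkeeping:
            raise ValueError(
                f"bookkeeping out of sync: recorded {self.bookkeeping}, recomputed {fresh}"
            )
        if sum(fresh["per_visit_type"].values()) != fresh["n_samples"]:
            raise ValueError("per-visit-type counts do not sum to n_samples")

    @property
    def n_samples(self) -> int:
        return self.bookkeeping["n_samples"]

    @property
    def n_patients(self) -> int:
        return self.bookkeeping["n_patients"]

    def aligned_metadata(self) -> pd.DataFrame:
        """Metadata rows in the abundance table's sample order."""
        return self.metadata.data.loc[self.table.sample_ids]


# ---------------------------------------------------------------------------
# loading


def _detect_kind(values: np.ndarray) -> str:
    """Integer-valued tables are counts, everything else relative."""
    if np.allclose(values, np.round(values)):
        return "counts"
    return "relative"


def load_abundance_tsv(path: str | Path, metadata_sample_ids: set[str] | None = None) -> GenusAbundanceTable:
    """Read a genus abundance TSV (samples as rows, first column sample id).

    A transposed table (genera as rows) is detected by comparing row and
    column labels against the metadata sample ids and auto-corrected with a
    warning.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if metadata_sample_ids:
        row_overlap = len(set(df.index.astype(str)) & metadata_sample_ids)
        col_overlap = len(set(df.columns.astype(str)) & metadata_sample_ids)
        if col_overlap > row_overlap:
            warnings.warn(
                f"abundance table at {path} looks transposed "
                f"(sample ids found in columns); auto-transposing",
                stacklevel=2,
            )
            df = df.T
    df.index = df.index.astype(str)
    values = df.to_numpy(dtype=float)
    kind = _detect_kind(values)
    if kind == "relative":
        # tolerate rounding in exported files, then renormalise exactly
        sums = values.sum(axis=1)
        if np.allclose(sums, 1.0, atol=1e-3):
            df = df.div(sums, axis=0)
        else:
            raise ValueError(
                "non-integer abundance table whose rows do not sum to 1; "
                "cannot determine kind"
            )
    return GenusAbundanceTable(df, kind=kind)


def load_biom_table(path: str | Path) -> GenusAbundanceTable:
    """Read a BIOM-format table (observations = genera) as counts/relative."""
    import biom

    bt = biom.load_table(str(path))
    df = bt.to_dataframe(dense=True).T  # biom stores observations x samples
    df.index = df.index.astype(str)
    return GenusAbundanceTable(df, kind=_detect_kind(df.to_numpy(dtype=float)))


def load_metadata_tsv(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "patient_id": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"metadata at {path} lacks a sample_id column")
    df = df.set_index("sample_id")
    return SampleMetadata(df)


def load_cohort(abundance_path: str | Path, metadata_path: str | Path) -> CohortDataset:
    """Load and cross-validate an abundance table and its metadata.

    Raises ``ValueError`` listing offending ids on any mismatch.
    """
    metadata = load_metadata_tsv(metadata_path)
    table = load_abundance_tsv(abundance_path, set(metadata.sample_ids))
    table_ids, meta_ids = set(table.sample_ids), set(metadata.sample_ids)
    if table_ids - meta_ids:
        raise ValueError(
            f"abundance samples missing from metadata: {sorted(table_ids - meta_ids)}"
        )
    # metadata covering extra samples is allowed; restrict to the table
    meta = SampleMetadata(metadata.data.loc[table.sample_ids].copy())
    return CohortDataset(table=table, metadata=meta)


# ---------------------------------------------------------------------------
# normalisation


def to_relative(table: GenusAbundanceTable) -> GenusAbundanceTable:
    """Convert counts to per-sample relative abundances (idempotent)."""
    if table.kind == "relative":
        return table
    values = table.values
    sums = values.sum(axis=1)
    zero = np.where(sums <= 0)[0]
    if zero.size:
        ids = [table.sample_ids[i] for i in zero]
        raise ValueError(f"samples with zero total abundance: {ids}")
    rel = pd.DataFrame(values / sums[:, None], index=table.data.index, columns=table.data.columns)
    return GenusAbundanceTable(rel, kind="relative")


def rarefy(
    table: GenusAbundanceTable, depth: int, seed: int | np.random.Generator = 0
) -> tuple[GenusAbundanceTable, list[str]]:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped and returned in
    the report list. Deterministic under a fixed seed.
    """
    if table.kind != "counts":
        raise ValueError("rarefaction requires a counts table")
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = np.round(table.values).astype(np.int64)
    totals = counts.sum(axis=1)
    kept_rows, kept_ids, dropped = [], [], []
    for i, sid in enumerate(table.sample_ids):
        if totals[i] < depth:
            dropped.append(sid)
            continue
        if totals[i] == depth:
            kept_rows.append(counts[i])
        else:
            kept_rows.append(rng.multivariate_hypergeometric(counts[i], depth))
        kept_ids.append(sid)
    if not kept_ids:
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    out = pd.DataFrame(np.asarray(kept_rows), index=kept_ids, columns=table.data.columns)
    return GenusAbundanceTable(out, kind="counts"), dropped


# ---------------------------------------------------------------------------
# writing


def save_cohort(dataset: CohortDataset, out_dir: str | Path) -> None:
    """Write the canonical dataset directory (table TSV, metadata TSV, JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g" if dataset.table.kind == "relative" else "%d"
    dataset.table.data.to_csv(out / "abundance.tsv", sep="\t", float_format=fmt, index_label="sample_id")
    dataset.metadata.data.to_csv(out / "metadata.tsv", sep="\t", index_label="sample_id")
    with open(out / "bookkeeping.json", "w") as fh:
        json.dump(dataset.bookkeeping, fh, indent=2)


def load_cohort_dir(path: str | Path) -> CohortDataset:
    """Load a dataset directory produced by :func:`save_cohort`."""
    p = Path(path)
    return load_cohort(p / "abundance.tsv", p / "metadata.tsv")
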