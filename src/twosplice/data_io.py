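"""Reading, filtering and reshaping isoform abundance tables.

Quantifiers such as Cufflinks, kallisto or RSEM emit per-sample isoform
abundances (FPKM or TPM).  This module turns those tables, plus a
sample-to-condition map, into per-gene units of complete log-abundance
vectors — the input the mixed model expects: for gene *m* with L isoforms,
every sample contributes one length-L vector.

Tables are held in long format (one row per gene/transcript/sample) and can
be read from long or wide TSV.  Filtering follows the usual conventions for
splicing analysis: drop low-abundance isoforms, then drop genes left with
fewer than two isoforms (a single-isoform gene admits no splicing contrast).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("twosplice")

__all__ = [
    "TableFormatError",
    "TableValidationError",
    "CompletenessError",
    "TableDialect",
    "IsoformExpressionTable",
    "SampleMetadata",
    "GeneData",
    "FilterReport",
    "read_isoform_table",
    "read_sample_metadata",
    "write_isoform_table",
    "log_transform",
    "filter_genes",
    "assemble_gene_data",
]


class TableFormatError(ValueError):
    """A required column or structural element is missing."""


class TableValidationError(ValueError):
    """Record-level contents violate an invariant (negative value, duplicate)."""


class CompletenessError(ValueError):
    """A sample is missing one or more isoform values for a gene."""


@dataclass(frozen=True)
class TableDialect:
    """Names the columns of an abundance TSV.

    ``layout`` is ``"long"`` (one value column) or ``"wide"`` (one column per
    sample; every column other than the gene and transcript ids is a sample).
    """

    layout: str = "long"
    gene_col: str = "gene_id"
    transcript_col: str = "transcript_id"
    sample_col: str = "sample_id"
    value_col: str = "abundance"

    def __post_init__(self) -> None:
        if self.layout not in ("long", "wide"):
            raise TableFormatError(f"unknown table layout {self.layout!r}")


@dataclass
class IsoformExpressionTable:
    """Long-format isoform abundance records with a raw/log scale flag.

    ``data`` has columns ``gene_id``, ``transcript_id``, ``sample_id``,
    ``abundance``; (gene, transcript, sample) triples are unique and each
    transcript belongs to exactly one gene.
    """

    data: pd.DataFrame
    scale: str = "raw"  # "raw" | "log"
    log_offset: float | None = None

    def __post_init__(self) -> None:
        required = ["gene_id", "transcript_id", "sample_id", "abundance"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise TableFormatError(f"table is missing column(s): {', '.join(missing)}")
        if self.scale not in ("raw", "log"):
            raise ValueError(f"scale must be 'raw' or 'log', got {self.scale!r}")
        if self.scale == "log" and (self.log_offset is None or self.log_offset <= 0):
            raise ValueError("log-scale table requires a positive log_offset")
        self._validate_records()

    def _validate_records(self) -> None:
        df = self.data
        dup = df.duplicated(["gene_id", "transcript_id", "sample_id"])
        if dup.any():
            row = df[dup].iloc[0]
            raise TableValidationError(
                "duplicate (gene, transcript, sample) record: "
                f"({row.gene_id}, {row.transcript_id}, {row.sample_id})"
            )
        multi = df.groupby("transcript_id")["gene_id"].nunique()
        bad = multi[multi > 1]
        if len(bad):
            raise TableValidationError(
                f"transcript {bad.index[0]!r} maps to more than one gene"
            )
        vals = df["abundance"].to_numpy(dtype=float)
        if self.scale == "raw":
            if np.isnan(vals).any():
                i = int(np.flatnonzero(np.isnan(vals))[0])
                raise TableValidationError(f"missing abundance at record {i}")
            if (vals < 0).any():
                i = int(np.flatnonzero(vals < 0)[0])
                raise TableValidationError(
                    f"negative abundance {vals[i]} at record {i} "
                    f"(gene {df.iloc[i].gene_id}, sample {df.iloc[i].sample_id})"
                )
        else:
            if not np.isfinite(vals).all():
                i = int(np.flatnonzero(~np.isfinite(vals))[0])
                raise TableValidationError(f"non-finite log abundance at record {i}")

    @property
    def n_records(self) -> int:
        return len(self.data)

    @property
    def gene_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["gene_id"]))

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample_id"]))


@dataclass
class SampleMetadata:
    """Sample-to-condition assignment with a fixed condition ordering.

    Condition levels are ordered lexicographically with the first level as
    the reference, unless ``reference`` pins a different level first.
    """

    assignments: pd.DataFrame  # columns sample_id, condition
    reference: str | None = None

    def __post_init__(self) -> None:
        missing = [c for c in ("sample_id", "condition") if c not in self.assignments.columns]
        if missing:
            raise TableFormatError(f"metadata is missing column(s): {', '.join(missing)}")
        if self.assignments["sample_id"].duplicated().any():
            dup = self.assignments.loc[self.assignments["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise TableValidationError(f"duplicate sample_id {dup!r} in metadata")
        levels = sorted(self.assignments["condition"].astype(str).unique())
        if len(levels) < 2:
            raise TableValidationError("metadata must contain at least two condition levels")
        if self.reference is not None:
            if self.reference not in levels:
                raise ValueError(f"reference level {self.reference!r} not among conditions {levels}")
            levels = [self.reference] + [lv for lv in levels if lv != self.reference]
        self.levels: list[str] = levels
        self.condition_of: dict[str, str] = dict(
            zip(self.assignments["sample_id"].astype(str), self.assignments["condition"].astype(str))
        )

    @property
    def J(self) -> int:
        return len(self.levels)


@dataclass
class GeneData:
    """One gene's complete log-abundance vectors, grouped by condition.

    ``y[j]`` is a ``(K_j, L)`` array: sample k of condition j holds the
    length-L vector (Y_jk1, ..., Y_jkL) of log abundances, isoforms in the
    order of ``isoform_ids``.
    """

    gene_id: str
    isoform_ids: list[str]
    condition_labels: list[str]
    y: list[np.ndarray]
    sample_ids: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = [np.asarray(a, dtype=float) for a in self.y]
        L = len(self.isoform_ids)
        if L < 2:
            raise ValueError(f"gene {self.gene_id}: needs >= 2 isoforms, got {L}")
        if len(self.y) != len(self.condition_labels):
            raise ValueError(f"gene {self.gene_id}: y blocks do not match condition labels")
        for lab, a in zip(self.condition_labels, self.y):
            if a.ndim != 2 or a.shape[1] != L:
                raise ValueError(f"gene {self.gene_id}, condition {lab}: block shape {a.shape} != (K, {L})")
            if not np.isfinite(a).all():
                raise CompletenessError(f"gene {self.gene_id}, condition {lab}: non-finite log abundance")

    @property
    def L(self) -> int:
        return len(self.isoform_ids)

    @property
    def J(self) -> int:
        return len(self.condition_labels)

    @property
    def K(self) -> list[int]:
        return [a.shape[0] for a in self.y]

    @property
    def N(self) -> int:
        return sum(self.K)

    def stacked(self) -> np.ndarray:
        """All sample vectors as one (N, L) array, conditions in order."""
        return np.vstack(self.y)


@dataclass(frozen=True)
class FilterReport:
    isoforms_in: int
    isoforms_dropped_low_abundance: int
    genes_in: int
    genes_dropped_few_isoforms: int
    records_in: int
    records_out: int


def read_isoform_table(path, dialect: TableDialect | None = None) -> IsoformExpressionTable:
    """Read an abundance TSV (long or wide layout) into a raw-scale table.

    Sample ids come from the header (wide) or the sample column (long); the
    input row order is preserved.
    """
    dialect = dialect or TableDialect()
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (dialect.gene_col, dialect.transcript_col):
        if col not in df.columns:
            raise TableFormatError(f"{path}: missing required column {col!r}")
    if dialect.layout == "long":
        for col in (dialect.sample_col, dialect.value_col):
            if col not in df.columns:
                raise TableFormatError(f"{path}: missing required column {col!r}")
        out = df[[dialect.gene_col, dialect.transcript_col, dialect.sample_col, dialect.value_col]].copy()
        out.columns = ["gene_id", "transcript_id", "sample_id", "abundance"]
    else:
        sample_cols = [c for c in df.columns if c not in (dialect.gene_col, dialect.transcript_col)]
        if not sample_cols:
            raise TableFormatError(f"{path}: wide table has no sample columns")
        out = df.melt(
            id_vars=[dialect.gene_col, dialect.transcript_col],
            value_vars=sample_cols,
            var_name="sample_id",
            value_name="abundance",
        )
        out = out.rename(columns={dialect.gene_col: "gene_id", dialect.transcript_col: "transcript_id"})
        # melt stacks by sample; restore input row-major order (row, then sample)
        n = len(df)
        order = np.arange(len(out)).reshape(len(sample_cols), n).T.ravel()
        out = out.iloc[order].reset_index(drop=True)
    try:
        out["abundance"] = out["abundance"].astype(float)
    except ValueError as exc:
        raise TableValidationError(f"{path}: non-numeric abundance value ({exc})") from exc
    return IsoformExpressionTable(out.reset_index(drop=True), scale="raw")


def read_sample_metadata(path, reference: str | None = None) -> SampleMetadata:
    """Read a two-column ``sample_id<TAB>condition`` metadata TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SampleMetadata(df, reference=reference)


def write_isoform_table(table: IsoformExpressionTable, path, layout: str = "long") -> None:
    """Write a table back to TSV in the long or wide dialect."""
    if layout == "long":
        table.data.to_csv(path, sep="\t", index=False)
    elif layout == "wide":
        wide = table.data.pivot(index=["gene_id", "transcript_id"], columns="sample_id", values="abundance")
        wide = wide[table.sample_ids]  # keep input sample order
        wide.reset_index().to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown layout {layout!r}")


def log_transform(table: IsoformExpressionTable, offset: float = 1.0) -> IsoformExpressionTable:
    """Replace every abundance a by ln(a + offset) and flag the table as log scale."""
    if table.scale == "log":
        raise ValueError("table is already on the log scale")
    if not (offset > 0) or not math.isfinite(offset):
        raise ValueError(f"log offset must be a positive finite real, got {offset}")
    out = table.data.copy()
    out["abundance"] = np.log(out["abundance"].to_numpy(dtype=float) + offset)
    return IsoformExpressionTable(out, scale="log", log_offset=offset)


def filter_genes(
    table: IsoformExpressionTable,
    min_isoforms: int = 2,
    min_mean_abundance: float = 1.0,
) -> tuple[IsoformExpressionTable, FilterReport]:
    """Drop low-abundance isoforms, then genes with too few remaining isoforms.

    An isoform is kept when its mean abundance across all samples is at least
    ``min_mean_abundance`` (on the raw FPKM/TPM scale, so filter before the
    log transform); a gene is kept when at least ``min_isoforms`` of its
    isoforms survive.
    """
    if min_isoforms < 2:
        raise ValueError("min_isoforms must be >= 2: a single-isoform gene admits no splicing contrast")
    if min_mean_abundance < 0:
        raise ValueError("min_mean_abundance must be non-negative")
    if table.scale != "raw":
        raise ValueError("filter on the raw abundance scale, before log_transform")
    df = table.data
    if df.empty:
        report = FilterReport(0, 0, 0, 0, 0, 0)
        return IsoformExpressionTable(df.copy(), scale="raw"), report

    iso_means = df.groupby("transcript_id", sort=False)["abundance"].mean()
    keep_iso = set(iso_means[iso_means >= min_mean_abundance].index)
    step1 = df[df["transcript_id"].isin(keep_iso)]

    iso_per_gene = step1.groupby("gene_id", sort=False)["transcript_id"].nunique()
    keep_gene = set(iso_per_gene[iso_per_gene >= min_isoforms].index)
    step2 = step1[step1["gene_id"].isin(keep_gene)].reset_index(drop=True)

    report = FilterReport(
        isoforms_in=df["transcript_id"].nunique(),
        isoforms_dropped_low_abundance=df["transcript_id"].nunique() - len(keep_iso),
        genes_in=df["gene_id"].nunique(),
        genes_dropped_few_isoforms=df["gene_id"].nunique() - step2["gene_id"].nunique(),
        records_in=len(df),
        records_out=len(step2),
    )
    logger.info(
        "filter_genes: dropped %d/%d isoforms (mean abundance < %g), %d/%d genes (< %d isoforms)",
        report.isoforms_dropped_low_abundance, report.isoforms_in, min_mean_abundance,
        report.genes_dropped_few_isoforms, report.genes_in, min_isoforms,
    )
    return IsoformExpressionTable(step2, scale="raw"), report


def assemble_gene_data(table: IsoformExpressionTable, meta: SampleMetadata) -> list[GeneData]:
    """Reshape a log-scale table into one :class:`GeneData` per gene.

    Isoforms are ordered lexicographically by transcript id; conditions follow
    ``meta.levels``.  Samples listed in the metadata but absent from the table
    are skipped with a warning (quantifiers may drop samples); a sample that
    is present but missing some isoform of a gene is an error — the model
    assumes complete per-sample vectors.
    """
    if table.scale != "log":
        raise ValueError("assemble_gene_data expects a log-scale table; call log_transform first")
    df = table.data
    unknown = set(df["sample_id"]) - set(meta.condition_of)
    if unknown:
        raise TableValidationError(
            f"sample(s) present in the table but absent from metadata: {sorted(unknown)[:5]}"
        )
    table_samples = set(df["sample_id"])
    skipped = [s for s in meta.condition_of if s not in table_samples]
    if skipped:
        logger.warning("assemble_gene_data: %d metadata sample(s) absent from the table, skipped: %s",
                       len(skipped), skipped[:5])

    genes: list[GeneData] = []
    for gene_id, gdf in df.groupby("gene_id", sort=True):
        isoforms = sorted(gdf["transcript_id"].unique())
        pivot = gdf.pivot(index="sample_id", columns="transcript_id", values="abundance")
        if pivot.isna().any().any():
            sample = pivot.index[pivot.isna().any(axis=1)][0]
            raise CompletenessError(
                f"gene {gene_id}: sample {sample} is missing one or more isoform values"
            )
        pivot = pivot[isoforms]
        blocks, labels, sample_lists = [], [], []
        for level in meta.levels:
            in_level = sorted(s for s in pivot.index if meta.condition_of[s] == level)
            if not in_level:
                continue
            blocks.append(pivot.loc[in_level].to_numpy(dtype=float))
            labels.append(level)
            sample_lists.append(in_level)
        genes.append(GeneData(str(gene_id), isoforms, labels, blocks, sample_lists))
    return genes
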