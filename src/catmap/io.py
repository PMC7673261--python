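"""Core data containers and readers/writers.

All tables travel as tab-separated UTF-8 text with a ``.`` decimal point,
deterministic column order, and no pandas index column, so that a
write → read cycle is byte-identical and results diff cleanly under
version control. Count matrices may alternatively be stored as a
MatrixMarket coordinate file with ``.rownames`` / ``.colnames`` sidecars.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "CountMatrix",
    "OrthologMap",
    "NormalizedMatrix",
    "ValidationError",
    "read_counts",
    "write_counts",
    "read_metadata",
    "write_metadata",
    "read_ortholog_map",
    "write_ortholog_map",
    "read_signature_table",
    "read_table",
    "write_table",
    "write_json",
    "validate_metadata",
]

META_COLUMNS = ["sample_id", "species", "tissue", "subtype", "subject_id"]

SEX_CHROMOSOMES = {"X", "Y", "chrX", "chrY", "x", "y"}


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _check_unique(values, what: str) -> None:
    idx = pd.Index(values)
    if idx.has_duplicates:
        dups = sorted(idx[idx.duplicated()].unique().tolist())
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class CountMatrix:
    """Integer gene × sample count matrix for one species.

    ``counts`` is a DataFrame indexed by gene ID with sample IDs as
    columns; entries are non-negative integers (unique-mapping read
    counts per gene).
    """

    counts: pd.DataFrame
    species: str = ""

    def __post_init__(self) -> None:
        _check_unique(self.counts.index, "gene IDs")
        _check_unique(self.counts.columns, "sample IDs")
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.round(values)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if values.size and (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        self.counts.index.name = "gene_id"

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class OrthologMap:
    """1:1 gene pairing between two species.

    ``pairs`` has columns ``gene_a`` and ``gene_b``; after construction
    every gene on either side appears in exactly one pair (bijective).
    """

    pairs: pd.DataFrame

    def __post_init__(self) -> None:
        self.pairs = self.pairs.reset_index(drop=True)[["gene_a", "gene_b"]]
        _check_unique(self.pairs["gene_a"], "species-A genes in ortholog map")
        _check_unique(self.pairs["gene_b"], "species-B genes in ortholog map")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def pair_ids(self) -> pd.Index:
        """Canonical cross-species gene identifiers (``geneA|geneB``)."""
        return pd.Index(
            self.pairs["gene_a"].astype(str) + "|" + self.pairs["gene_b"].astype(str),
            name="gene_id",
        )


@dataclass
class NormalizedMatrix:
    """Continuous gene × sample matrix at a named normalization stage.

    ``stage`` advances only forward through ``vst`` →
    ``subject_regressed`` → ``quantile_normalized``. ``fallback`` marks
    genes whose mixed-model subject regression had a singular fit (zero
    random-intercept variance) and therefore kept their input values.
    """

    values: pd.DataFrame
    stage: str
    species: str = ""
    fallback: pd.Series = field(default=None)  # type: ignore[assignment]

    STAGES = ("vst", "subject_regressed", "quantile_normalized")

    def __post_init__(self) -> None:
        if self.stage not in self.STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValidationError("normalized values must be finite")
        if self.fallback is None:
            self.fallback = pd.Series(False, index=self.values.index)
        self.fallback = self.fallback.reindex(self.values.index, fill_value=False)
        self.values.index.name = "gene_id"

    def advance(self, values: pd.DataFrame, stage: str, fallback=None) -> "NormalizedMatrix":
        if self.STAGES.index(stage) < self.STAGES.index(self.stage):
            raise ValidationError(f"stage may not move backward: {self.stage} -> {stage}")
        fb = self.fallback if fallback is None else fallback
        return NormalizedMatrix(values=values, stage=stage, species=self.species, fallback=fb)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# Count matrices


def read_counts(path, format: str = "tsv", species: str = "") -> CountMatrix:
    """Read a gene × sample count matrix.

    ``format='tsv'``: dense table, first column gene IDs, header row of
    sample IDs. ``format='mtx'``: MatrixMarket coordinate file with
    ``<stem>.rownames`` / ``<stem>.colnames`` sidecars (one ID per line).
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    elif format == "mtx":
        mat = scipy.io.mmread(path)
        genes = Path(str(path) + ".rownames").read_text().splitlines()
        samples = Path(str(path) + ".colnames").read_text().splitlines()
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        df = pd.DataFrame(dense, index=genes, columns=samples)
    else:
        raise ValueError(f"unknown count format {format!r}")
    if df.shape[0] and not all(
        np.issubdtype(t, np.integer) or np.issubdtype(t, np.floating) for t in df.dtypes
    ):
        raise ValidationError(f"non-numeric entries in count matrix {path}")
    return CountMatrix(counts=df, species=species)


def write_counts(cm: CountMatrix, path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        cm.counts.to_csv(path, sep="\t", lineterminator="\n")
    elif format == "mtx":
        sparse = scipy.sparse.coo_matrix(cm.counts.to_numpy())
        scipy.io.mmwrite(str(path), sparse)
        Path(str(path) + ".rownames").write_text("\n".join(cm.gene_ids) + "\n")
        Path(str(path) + ".colnames").write_text("\n".join(cm.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown count format {format!r}")


# ---------------------------------------------------------------------------
# Sample metadata


def validate_metadata(meta: pd.DataFrame, cm: CountMatrix | None = None) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata missing columns: {missing}")
    _check_unique(meta["sample_id"], "sample IDs in metadata")
    if cm is not None:
        absent = sorted(set(cm.sample_ids) - set(meta["sample_id"]))
        if absent:
            raise ValidationError(f"samples without metadata: {absent}")
    return meta


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    return validate_metadata(meta)


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta[META_COLUMNS].to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Ortholog maps


def build_ortholog_map(
    pairs: pd.DataFrame,
    chrom_a: pd.Series | None = None,
    chrom_b: pd.Series | None = None,
) -> OrthologMap:
    """Reduce a many-to-many homology table to its strict 1:1 subset.

    Every gene participating in more than one pair is dropped entirely
    (both of its rows), matching BioMart's one-to-one export semantics.
    When chromosome annotations are supplied, pairs touching a sex
    chromosome are removed to avoid donor-sex driven variation.
    """
    df = pairs.copy().reset_index(drop=True)
    if chrom_a is not None:
        on_sex = chrom_a.reset_index(drop=True).astype(str).isin(SEX_CHROMOSOMES)
        on_sex |= chrom_b.reset_index(drop=True).astype(str).isin(SEX_CHROMOSOMES)
        n_sex = int(on_sex.sum())
        if n_sex:
            warnings.warn(f"dropping {n_sex} sex-chromosome ortholog pairs")
        df = df[~on_sex.to_numpy()]
    multi_a = df["gene_a"].duplicated(keep=False)
    multi_b = df["gene_b"].duplicated(keep=False)
    ambiguous = multi_a | multi_b
    if ambiguous.any():
        warnings.warn(
            f"dropping {int(ambiguous.sum())} rows involved in non-1:1 homology relations"
        )
        df = df[~ambiguous.to_numpy()]
    if df.empty:
        raise ValidationError("no 1:1 ortholog pairs remain after filtering")
    return OrthologMap(pairs=df.reset_index(drop=True))


def read_ortholog_map(path, chromosome_annotation: bool | None = None) -> OrthologMap:
    """Read a two-column (A-gene, B-gene) TSV, BioMart-export style.

    Optional third/fourth columns carry the chromosome of each gene;
    when present (auto-detected unless ``chromosome_annotation`` is
    forced), sex-chromosome pairs are removed.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"ortholog map {path} needs at least two columns")
    cols = list(df.columns)
    out = df.rename(columns={cols[0]: "gene_a", cols[1]: "gene_b"})
    has_chrom = df.shape[1] >= 4 if chromosome_annotation is None else chromosome_annotation
    if has_chrom:
        if df.shape[1] < 4:
            raise ValidationError("chromosome annotation requested but columns 3/4 missing")
        return build_ortholog_map(out, chrom_a=df[cols[2]], chrom_b=df[cols[3]])
    return build_ortholog_map(out[["gene_a", "gene_b"]])


def write_ortholog_map(om: OrthologMap, path) -> None:
    om.pairs.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Signature tables and generic result tables


def read_signature_table(path, rank_col: str | None = None) -> pd.DataFrame:
    """Read an external signature table: gene, cluster, ranking statistic.

    Columns beyond ``gene_id`` and ``cluster`` are candidate ranking
    statistics (AUC, avg_logFC, EMD×AUC score, ...); ``rank_col``
    selects one and the result gains a canonical ``rank_stat`` column.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "cluster"):
        if col not in df.columns:
            raise ValidationError(f"signature table missing column {col!r}")
    if rank_col is not None:
        if rank_col not in df.columns:
            raise ValidationError(f"signature table has no column {rank_col!r}")
        df = df.assign(rank_stat=pd.to_numeric(df[rank_col]))
        if not np.all(np.isfinite(df["rank_stat"])):
            raise ValidationError("ranking statistic contains non-finite values")
    return df


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
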