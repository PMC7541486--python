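"""Data model, file I/O, QC filters and normalization for annotated count matrices.

The central container is :class:`AnnotatedCounts`, a thin validating wrapper
around an :class:`anndata.AnnData` holding a sparse integer cell × gene matrix
(cells in rows throughout the package) with per-cell sample, condition and
hierarchical subtype annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

CONDITIONS = ("control", "case")
SUBTYPE_LEVELS = ("level1", "level2", "level3", "level4")
REQUIRED_OBS = ("sample_id", "condition") + SUBTYPE_LEVELS + ("class",)


class ValidationError(ValueError):
    """Raised when input data violate the container contracts."""


class ConfigurationError(ValueError):
    """Raised when a configuration value is invalid; names the field."""


class AnnotatedCounts:
    """Sparse integer cell × gene matrix with sample/condition/subtype labels.

    Parameters
    ----------
    adata
        AnnData with raw counts in ``X`` and the obs columns
        ``sample_id, condition, level1..level4, class``. ``condition`` must be
        ``"control"`` or ``"case"`` and constant within each sample; cell and
        gene identifiers must be unique.
    """

    def __init__(self, adata: ad.AnnData):
        obs = adata.obs
        missing = [c for c in REQUIRED_OBS if c not in obs.columns]
        if missing:
            raise ValidationError(f"missing metadata columns: {missing}")
        bad = set(obs["condition"].unique()) - set(CONDITIONS)
        if bad:
            raise ValidationError(f"unknown condition labels: {sorted(bad)}")
        if obs.index.duplicated().any():
            dups = obs.index[obs.index.duplicated()].tolist()[:5]
            raise ValidationError(f"duplicate cell ids: {dups}")
        if adata.var_names.duplicated().any():
            raise ValidationError("duplicate gene ids")
        per_sample = obs.groupby("sample_id", observed=True)["condition"].nunique()
        mixed = per_sample[per_sample > 1].index.tolist()
        if mixed:
            raise ValidationError(f"condition not constant within samples: {mixed}")
        if not sp.issparse(adata.X):
            adata.X = sp.csr_matrix(adata.X)
        if adata.X.nnz and adata.X.min() < 0:
            raise ValidationError("counts must be non-negative")
        self.adata = adata

    # -- convenience accessors -------------------------------------------------
    @property
    def X(self) -> sp.spmatrix:
        return self.adata.X

    @property
    def obs(self) -> pd.DataFrame:
        return self.adata.obs

    @property
    def genes(self) -> pd.Index:
        return self.adata.var_names

    @property
    def n_cells(self) -> int:
        return self.adata.n_obs

    @property
    def n_genes(self) -> int:
        return self.adata.n_vars

    @property
    def samples(self) -> list[str]:
        return sorted(self.obs["sample_id"].unique())

    def condition_of_sample(self) -> pd.Series:
        return self.obs.groupby("sample_id", observed=True)["condition"].first()

    def subset_cells(self, mask: np.ndarray) -> "AnnotatedCounts":
        return AnnotatedCounts(self.adata[np.asarray(mask)].copy())

    def subset_genes(self, mask: np.ndarray) -> "AnnotatedCounts":
        return AnnotatedCounts(self.adata[:, np.asarray(mask)].copy())

    def subtypes(self, level: str = "level4") -> list[str]:
        return sorted(self.obs[level].unique())

    def class_of_subtype(self, level: str = "level4") -> pd.Series:
        """Map subtype name -> class (principal | interneuron)."""
        return self.obs.groupby(level, observed=True)["class"].first()

    # -- I/O -------------------------------------------------------------------
    def write(self, out_dir: str | Path) -> None:
        """Write MTX (cells in rows) + genes.tsv + cells.tsv."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(
            str(out / "matrix.mtx"),
            sp.coo_matrix(self.X),
            comment="cells in rows, genes in columns",
        )
        pd.Series(self.genes, name="gene_id").to_csv(
            out / "genes.tsv", sep="\t", index=False
        )
        meta = self.obs.reset_index(names="cell_id")
        meta.to_csv(out / "cells.tsv", sep="\t", index=False)


def load_counts(
    mtx_path: str | Path, genes_path: str | Path, metadata_path: str | Path
) -> AnnotatedCounts:
    """Load a cohort from MatrixMarket counts plus gene and cell-metadata TSVs.

    The metadata must cover every matrix row; rows are matched to metadata by
    order of ``cell_id``.
    """
    for p in (mtx_path, genes_path, metadata_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    counts = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    genes = pd.read_csv(genes_path, sep="\t")["gene_id"].astype(str)
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"cell_id": str})
    if "cell_id" not in meta.columns:
        raise ValidationError("metadata must contain a cell_id column")
    if counts.shape[0] != len(meta):
        raise ValidationError(
            f"dimension mismatch: matrix has {counts.shape[0]} cells, "
            f"metadata has {len(meta)}"
        )
    if counts.shape[1] != len(genes):
        raise ValidationError(
            f"dimension mismatch: matrix has {counts.shape[1]} genes, "
            f"gene table has {len(genes)}"
        )
    meta = meta.set_index("cell_id")
    adata = ad.AnnData(X=counts, obs=meta, var=pd.DataFrame(index=pd.Index(genes, name="gene_id")))
    return AnnotatedCounts(adata)


def load_cohort_dir(path: str | Path) -> AnnotatedCounts:
    path = Path(path)
    return load_counts(path / "matrix.mtx", path / "genes.tsv", path / "cells.tsv")


# -- QC ---------------------------------------------------------------------


def mito_genes_by_prefix(genes: pd.Index, prefix: str = "MT-") -> list[str]:
    """Convenience: mitochondrial gene ids by name prefix."""
    return [g for g in genes if g.upper().startswith(prefix.upper())]


def qc_filter_cells(
    data: AnnotatedCounts,
    profile: str,
    mito_gene_ids: list[str] | None = None,
    *,
    mito_max_droplet: float = 0.08,
    min_genes_plate: int = 2000,
    max_reads_plate: int = 1_000_000,
    mito_max_plate: float = 0.05,
    min_cells_per_gene_plate: int = 5,
) -> AnnotatedCounts:
    """Remove low-quality cells following the platform-specific rules.

    ``droplet`` removes cells whose mitochondrial fraction exceeds 8%.
    ``plate`` removes cells with fewer than 2000 detected genes, more than one
    million total reads, or mitochondrial fraction above 5%, then drops genes
    present in fewer than 5 cells.
    """
    if profile not in ("droplet", "plate"):
        raise ConfigurationError(f"profile must be droplet or plate, got {profile!r}")
    mito_gene_ids = mito_gene_ids or []
    X = sp.csr_matrix(data.X)
    totals = np.asarray(X.sum(axis=1)).ravel()
    mito_mask = data.genes.isin(mito_gene_ids)
    mito_counts = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)

    if profile == "droplet":
        keep = mito_frac <= mito_max_droplet
    else:
        n_genes_detected = np.asarray((X > 0).sum(axis=1)).ravel()
        keep = (
            (n_genes_detected >= min_genes_plate)
            & (totals <= max_reads_plate)
            & (mito_frac <= mito_max_plate)
        )
    if not keep.any():
        raise ValidationError(
            "QC removed every cell; review thresholds against the input data"
        )
    out = data.subset_cells(keep)
    if profile == "plate":
        cells_per_gene = np.asarray((out.X > 0).sum(axis=0)).ravel()
        out = out.subset_genes(cells_per_gene >= min_cells_per_gene_plate)
    return out


def filter_samples_by_coverage(
    data: AnnotatedCounts,
    min_cells: int = 5,
    max_sparse_subtypes: int = 5,
    subtype_level: str = "level4",
) -> list[str]:
    """Retain samples unless more than ``max_sparse_subtypes`` subtypes have
    fewer than ``min_cells`` cells in them (strict inequality on both counts)."""
    counts = (
        data.obs.groupby(["sample_id", subtype_level], observed=False)
        .size()
        .unstack(fill_value=0)
    )
    # subtypes absent from a sample count as sparse
    all_subtypes = data.subtypes(subtype_level)
    counts = counts.reindex(columns=all_subtypes, fill_value=0)
    n_sparse = (counts < min_cells).sum(axis=1)
    return sorted(n_sparse[n_sparse <= max_sparse_subtypes].index)


# -- normalization ----------------------------------------------------------


@dataclass
class NormalizedMatrix:
    """Total-count normalized cells × genes matrix (dense float)."""

    matrix: np.ndarray
    scale: float
    log1p: bool
    cells: pd.Index
    genes: pd.Index

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.cells, columns=self.genes)


def total_count_normalize(
    data: AnnotatedCounts, scale: float = 10_000.0, log1p: bool = False
) -> NormalizedMatrix:
    """Scale every cell to a constant total, optionally log(1+x)-transform."""
    X = sp.csr_matrix(data.X, dtype=float)
    totals = np.asarray(X.sum(axis=1)).ravel()
    zero = np.where(totals == 0)[0]
    if zero.size:
        ids = data.obs.index[zero[:10]].tolist()
        raise ValidationError(f"all-zero cells cannot be normalized: {ids}")
    mat = X.multiply(scale / totals[:, None]).toarray()
    if log1p:
        mat = np.log1p(mat)
    return NormalizedMatrix(mat, scale, log1p, data.obs.index, data.genes)


# -- label-match filter ------------------------------------------------------


@dataclass
class MatchTable:
    """Counts n[i, j] of cells of local type i labeled as external type j."""

    counts: pd.DataFrame
    retained: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValidationError("match counts must be non-negative")
        if self.retained is None:
            self.retained = pd.DataFrame(
                True, index=self.counts.index, columns=self.counts.columns
            )


def filter_label_matches(
    match: MatchTable, min_count: int = 2, min_fraction: float = 0.05
) -> MatchTable:
    """Keep a match (i, j) iff n[i,j] >= min_count and its row fraction >= min_fraction.

    Singleton matches (n = 1) and matches carrying < 5% of a local type's cells
    are treated as label-transfer noise and dropped.
    """
    counts = match.counts.copy()
    retained = pd.DataFrame(False, index=counts.index, columns=counts.columns)
    for i in counts.index:
        row = counts.loc[i]
        total = row.sum()
        if total == 0:
            warnings.warn(f"local type {i!r} has no cells; skipped")
            continue
        retained.loc[i] = (row >= min_count) & (row / total >= min_fraction)
    filtered = counts.where(retained, 0)
    return MatchTable(filtered, retained)


# -- gene-set / gene-list I/O -------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a tab-separated GMT file: set name, description, member genes."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "") -> None:
    lines = [
        "\t".join([name, description or name] + list(genes))
        for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One symbol per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_list(genes: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")
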