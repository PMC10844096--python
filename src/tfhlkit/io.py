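"""Readers and writers for every on-disk dialect the pipeline touches.

All tabular formats are plain text (TSV/CSV, optionally gzipped); the count
matrix uses MatrixMarket coordinate format with the CellRanger triplet layout
(matrix.mtx + features.tsv + barcodes.tsv, 1-based indices on disk, 0-based in
memory). Genomic coordinates on disk are 1-based inclusive.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "FormatError",
    "CANONICAL_CHROMOSOMES",
    "chromosome_sort_key",
    "read_count_matrix",
    "write_count_matrix",
    "read_contigs",
    "write_contigs",
    "read_pileup",
    "write_pileup",
    "read_gene_positions",
    "write_gene_positions",
    "read_cellmeta",
    "write_cellmeta",
    "read_spatial",
    "write_spatial",
]


class FormatError(ValueError):
    """Raised when an input file violates its documented dialect."""


#: hg38-style autosome/sex-chromosome order; anything else sorts lexically after.
CANONICAL_CHROMOSOMES = [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]
_CHROM_RANK = {c: i for i, c in enumerate(CANONICAL_CHROMOSOMES)}


def chromosome_sort_key(chrom: str) -> tuple:
    """Sort key placing chr1..chr22, chrX, chrY first, unknown names after."""
    if chrom in _CHROM_RANK:
        return (0, _CHROM_RANK[chrom], "")
    return (1, 0, chrom)


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass
class CountMatrix:
    """Sparse genes x cells UMI count matrix with gene and barcode indices."""

    genes: list
    barcodes: list
    counts: sp.csr_matrix  # genes x cells, non-negative integers

    def __post_init__(self):
        self.genes = list(self.genes)
        self.barcodes = list(self.barcodes)
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        if self.counts.shape != (len(self.genes), len(self.barcodes)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            dupes = pd.Index(self.barcodes)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise FormatError(f"duplicate barcodes: {dupes[:5]}")
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.floor(data))):
            raise FormatError("counts must be non-negative integers")
        self.counts.data = self.counts.data.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def gene_index(self) -> pd.Index:
        return pd.Index(self.genes)

    def barcode_index(self) -> pd.Index:
        return pd.Index(self.barcodes)

    def subset_cells(self, barcodes: Sequence[str]) -> "CountMatrix":
        idx = self.barcode_index().get_indexer(list(barcodes))
        if np.any(idx < 0):
            missing = [b for b, i in zip(barcodes, idx) if i < 0]
            raise KeyError(f"unknown barcodes: {missing[:5]}")
        return CountMatrix(self.genes, list(barcodes), self.counts[:, idx])

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def log_cp10k(self) -> np.ndarray:
        """Dense genes x cells matrix of log2(CP10K + 1) values.

        CP10K = counts scaled so each cell sums to 10,000 (cells with zero
        total are left at zero).
        """
        totals = np.asarray(self.counts.sum(axis=0)).ravel().astype(float)
        scale = np.divide(1e4, totals, out=np.zeros_like(totals), where=totals > 0)
        dense = self.dense().astype(float) * scale[None, :]
        return np.log2(dense + 1.0)


# ---------------------------------------------------------------------------
# MatrixMarket triplet


def read_count_matrix(path) -> CountMatrix:
    """Read a CellRanger-style triplet directory (matrix.mtx, features.tsv,
    barcodes.tsv; .gz variants transparently)."""
    path = Path(path)

    def _find(stem):
        for name in (stem, stem + ".gz"):
            p = path / name
            if p.exists():
                return p
        raise FormatError(f"missing {stem} under {path}")

    mtx_path = _find("matrix.mtx")
    with _open_text(mtx_path, "rb" if mtx_path.suffix == ".gz" else "rb") as fh:
        mat = scipy.io.mmread(fh)
    mat = sp.csr_matrix(mat)
    genes = pd.read_csv(_find("features.tsv"), sep="\t", header=None)[0].tolist()
    barcodes = pd.read_csv(_find("barcodes.tsv"), sep="\t", header=None)[0].tolist()
    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"matrix header {mat.shape} disagrees with {len(genes)} features / "
            f"{len(barcodes)} barcodes"
        )
    return CountMatrix(genes, barcodes, mat)


def write_count_matrix(matrix: CountMatrix, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(path / "matrix.mtx"), matrix.counts.tocoo(), field="integer")
    pd.Series(matrix.genes).to_csv(path / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(matrix.barcodes).to_csv(path / "barcodes.tsv", sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# 10x contig annotations

CONTIG_COLUMNS = ["barcode", "chain", "v_gene", "j_gene", "cdr3", "cdr3_nt", "productive", "umis"]
VALID_CHAINS = {"TRA", "TRB", "IGH", "IGK", "IGL"}
_TRUE_STRINGS = {"true"}


def read_contigs(path) -> pd.DataFrame:
    """Read a 10x filtered_contig_annotations.csv-dialect table.

    `productive` parses case-insensitive "true" to True and anything else
    (False/None/empty) to False; rows keep their file order. The amino-acid
    CDR3 column `cdr3` is exposed as `cdr3_aa`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CONTIG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"contig table missing columns: {missing}")
    out = df[CONTIG_COLUMNS].copy()
    bad = ~out["chain"].isin(VALID_CHAINS)
    if bad.any():
        raise FormatError(f"unknown chains: {sorted(out.loc[bad, 'chain'].unique())}")
    out["productive"] = out["productive"].str.lower().isin(_TRUE_STRINGS)
    out["umis"] = pd.to_numeric(out["umis"], errors="raise").astype(int)
    if (out["umis"] < 0).any():
        raise FormatError("negative umi counts")
    empty_nt = out["productive"] & (out["cdr3_nt"].str.len() == 0)
    if empty_nt.any():
        raise FormatError("productive contig with empty cdr3_nt")
    return out.rename(columns={"cdr3": "cdr3_aa"})


def write_contigs(contigs: pd.DataFrame, path) -> None:
    out = contigs.rename(columns={"cdr3_aa": "cdr3"})[CONTIG_COLUMNS].copy()
    out["productive"] = np.where(out["productive"].astype(bool), "True", "False")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pileups

PILEUP_COLUMNS = ["barcode", "locus", "ref_reads", "alt_reads"]


def read_pileup(path) -> pd.DataFrame:
    """Per-cell x per-locus read pileup TSV; adds total = ref + alt."""
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str, "locus": str})
    missing = [c for c in PILEUP_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"pileup missing columns: {missing}")
    for col in ("ref_reads", "alt_reads"):
        df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
        if (df[col] < 0).any():
            raise FormatError(f"negative {col}")
    df["total"] = df["ref_reads"] + df["alt_reads"]
    return df[PILEUP_COLUMNS + ["total"]]


def write_pileup(pileup: pd.DataFrame, path) -> None:
    pileup[PILEUP_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene positions


def read_gene_positions(path) -> pd.DataFrame:
    """Gene -> (chromosome, start, end), 1-based inclusive, one row per gene."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str})
    missing = [c for c in ("gene", "chrom", "start", "end") if c not in df.columns]
    if missing:
        raise FormatError(f"gene positions missing columns: {missing}")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["start"] < 1).any() or (df["end"] < 1).any():
        raise FormatError("genomic coordinates are 1-based and must be >= 1")
    if (df["start"] > df["end"]).any():
        bad = df.loc[df["start"] > df["end"], "gene"].tolist()
        raise FormatError(f"start > end for genes: {bad[:5]}")
    if df["gene"].duplicated().any():
        raise FormatError("duplicate gene rows in position table")
    return df[["gene", "chrom", "start", "end"]]


def write_gene_positions(positions: pd.DataFrame, path) -> None:
    positions[["gene", "chrom", "start", "end"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Cell metadata

TISSUES = {"LN", "PB"}
STATUSES = {"ND", "RR", "control"}
CELLMETA_COLUMNS = ["barcode", "sample", "patient", "tissue", "status", "cluster"]


def read_cellmeta(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in CELLMETA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"cell metadata missing columns: {missing}")
    if df["barcode"].duplicated().any():
        raise FormatError("duplicate barcodes in cell metadata")
    bad_tissue = ~df["tissue"].isin(TISSUES)
    if bad_tissue.any():
        raise FormatError(f"unknown tissue values: {sorted(df.loc[bad_tissue, 'tissue'].unique())}")
    bad_status = ~df["status"].isin(STATUSES)
    if bad_status.any():
        raise FormatError(f"unknown status values: {sorted(df.loc[bad_status, 'status'].unique())}")
    return df[CELLMETA_COLUMNS]


def write_cellmeta(meta: pd.DataFrame, path) -> None:
    meta[CELLMETA_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Spatial cell tables (segmented IMC centroids)

SPATIAL_COLUMNS = ["image_id", "x_um", "y_um", "cell_type"]


def read_spatial(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"image_id": str, "cell_type": str})
    missing = [c for c in SPATIAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"spatial table missing columns: {missing}")
    df["x_um"] = df["x_um"].astype(float)
    df["y_um"] = df["y_um"].astype(float)
    if (df["x_um"] < 0).any() or (df["y_um"] < 0).any():
        raise FormatError("negative spatial coordinates")
    return df[SPATIAL_COLUMNS]


def write_spatial(cells: pd.DataFrame, path) -> None:
    cells[SPATIAL_COLUMNS].to_csv(path, index=False)
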