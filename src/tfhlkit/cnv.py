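"""Expression-based relative copy-number inference, chromosome-level calls,
CNV scores, subclone clustering, and clone trees.

The procedure follows the standard sliding-window approach for inferring
copy number from scRNA-seq: counts are library-size normalized (CP10K),
log2(x+1)-transformed, centered per gene on a reference (non-malignant) cell
set, clipped, smoothed along genomic position with a centered moving average
within each chromosome, and median-centered per cell. Genes on a chromosome
gained at dosage d shift by about log2(d) (0.585 for a 1.5x gain), which the
chromosome-level caller binarizes.

Subclones are Ward-linkage clusters of the smoothed profiles; the clone tree
is neighbor joining on Euclidean distances among subclone mean profiles plus
an all-neutral synthetic root, so branch order reflects stepwise accumulation
of CNV events.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .io import CountMatrix, chromosome_sort_key

logger = logging.getLogger(__name__)

__all__ = [
    "CNVProfile",
    "compute_relative_expression",
    "smooth_by_position",
    "call_chromosome_cnv",
    "cnv_score",
    "cluster_subclones",
    "build_clone_tree",
]


@dataclass
class CNVProfile:
    """Per-cell positionally smoothed log2-ratio profile.

    ``values`` is cells x genes, genes strictly ordered by (chromosome,
    start); ``chroms`` aligns with the gene axis.
    """

    values: np.ndarray
    barcodes: list
    genes: list
    chroms: np.ndarray
    window: int

    def chromosomes(self) -> list:
        seen = dict.fromkeys(self.chroms)
        return list(seen)


def _ordered_genes(counts: CountMatrix, positions: pd.DataFrame, min_genes_per_chrom: int):
    pos = positions.set_index("gene")
    shared = [g for g in counts.genes if g in pos.index]
    dropped = counts.n_genes - len(shared)
    if dropped:
        logger.info("dropped %d genes without genomic positions", dropped)
    if not shared:
        raise ValueError("no genes with genomic positions")
    sub = pos.loc[shared].reset_index()
    sub["_ckey"] = sub["chrom"].map(chromosome_sort_key)
    sub = sub.sort_values(["_ckey", "start", "gene"], kind="mergesort")
    n_per = sub.groupby("chrom")["gene"].count()
    thin = n_per[n_per < min_genes_per_chrom]
    if len(thin):
        logger.info("dropping chromosomes with <%d genes: %s", min_genes_per_chrom, list(thin.index))
        sub = sub[~sub["chrom"].isin(thin.index)]
    if sub.empty:
        raise ValueError("no chromosome retains enough positioned genes")
    return sub["gene"].tolist(), sub["chrom"].to_numpy()


def compute_relative_expression(
    counts: CountMatrix,
    positions: pd.DataFrame,
    reference_cells,
    clip: float = 1.0,
    min_genes_per_chrom: int = 5,
) -> tuple[np.ndarray, list, np.ndarray]:
    """Per-gene log2 expression ratios relative to the reference cell mean.

    Returns ``(matrix cells x genes, ordered gene list, chromosome array)``.
    All cells of the matrix (reference included) are profiled; the reference
    set defines the per-gene centering.
    """
    reference_cells = list(reference_cells)
    if not reference_cells:
        raise ValueError("empty reference cell set")
    genes, chroms = _ordered_genes(counts, positions, min_genes_per_chrom)
    logm = counts.log_cp10k()  # genes x cells
    gidx = counts.gene_index().get_indexer(genes)
    logm = logm[gidx, :]
    ridx = counts.barcode_index().get_indexer(reference_cells)
    if np.any(ridx < 0):
        raise KeyError("reference barcodes missing from the matrix")
    ref_mean = logm[:, ridx].mean(axis=1)
    rel = (logm - ref_mean[:, None]).T  # cells x genes
    np.clip(rel, -clip, clip, out=rel)
    return rel, genes, chroms


def _moving_average(block: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 1 with shrinking edge windows."""
    df = pd.DataFrame(block)
    return df.T.rolling(window, center=True, min_periods=1).mean().T.to_numpy()


def smooth_by_position(
    rel: np.ndarray,
    genes: list,
    chroms: np.ndarray,
    barcodes,
    window: int = 101,
) -> CNVProfile:
    """Smooth log2 ratios along each chromosome and median-center per cell.

    The moving average is centered with shrinking windows at chromosome
    edges; a window wider than twice the smallest chromosome is shrunk for
    that chromosome with a warning. Median-centering removes per-cell
    offsets that would otherwise mimic whole-genome dosage shifts.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    out = np.empty_like(rel, dtype=float)
    for chrom in dict.fromkeys(chroms):
        cols = np.flatnonzero(chroms == chrom)
        w = window
        if w > 2 * cols.size:
            w = max(1, 2 * (cols.size // 2) + 1)
            warnings.warn(f"window {window} too wide for {chrom} ({cols.size} genes); using {w}")
        out[:, cols] = _moving_average(rel[:, cols], w)
    out -= np.median(out, axis=1, keepdims=True)
    return CNVProfile(values=out, barcodes=list(barcodes), genes=list(genes),
                      chroms=np.asarray(chroms), window=window)


def call_chromosome_cnv(
    profile: CNVProfile,
    gain_threshold: float = 0.1,
    loss_threshold: float = -0.1,
    min_window_fraction: float = 0.5,
) -> pd.DataFrame:
    """Per-cell, per-chromosome {gain, neutral, loss} calls.

    A chromosome is called gained in a cell when the fraction of its smoothed
    windows above ``gain_threshold`` exceeds ``min_window_fraction`` (loss is
    symmetric); when both directions qualify, the one with the strictly
    larger supporting fraction wins, ties resolving to neutral. Returns a
    long DataFrame (barcode, chrom, state, frac_gain, frac_loss).
    """
    if gain_threshold <= loss_threshold:
        raise ValueError("gain threshold must exceed loss threshold")
    rows = []
    for chrom in profile.chromosomes():
        cols = profile.chroms == chrom
        block = profile.values[:, cols]
        frac_gain = (block > gain_threshold).mean(axis=1)
        frac_loss = (block < loss_threshold).mean(axis=1)
        state = np.full(len(profile.barcodes), "neutral", dtype=object)
        gain_ok = frac_gain > min_window_fraction
        loss_ok = frac_loss > min_window_fraction
        state[gain_ok & ~loss_ok] = "gain"
        state[loss_ok & ~gain_ok] = "loss"
        both = gain_ok & loss_ok
        state[both & (frac_gain > frac_loss)] = "gain"
        state[both & (frac_loss > frac_gain)] = "loss"
        for i, bc in enumerate(profile.barcodes):
            rows.append((bc, chrom, state[i], float(frac_gain[i]), float(frac_loss[i])))
    return pd.DataFrame(rows, columns=["barcode", "chrom", "state", "frac_gain", "frac_loss"])


def cnv_score(profile: CNVProfile) -> pd.Series:
    """Per-cell copy-number aberrance: mean squared smoothed log2 ratio."""
    return pd.Series(np.mean(profile.values**2, axis=1), index=profile.barcodes, name="cnv_score")


def cluster_subclones(profile: CNVProfile, k: int, linkage: str = "ward") -> pd.Series:
    """Hierarchical subclone labels (1..k) from the smoothed profiles."""
    n = len(profile.barcodes)
    if n < 2:
        raise ValueError("need at least two cells")
    if k > n:
        raise ValueError(f"k={k} exceeds {n} cells")
    Z = sch.linkage(profile.values, method=linkage)
    labels = sch.fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=profile.barcodes, name="subclone")


def build_clone_tree(mean_profiles: pd.DataFrame, root_name: str = "neutral") -> TreeNode:
    """Neighbor-joining clone tree over subclone mean profiles.

    ``mean_profiles`` is subclone x genes. An all-neutral (zero) profile is
    appended and the tree is rooted at it, so root-to-leaf paths order the
    accumulation of copy-number events. Returns an skbio TreeNode (write
    Newick with ``tree.write``).
    """
    if mean_profiles.empty:
        raise ValueError("no subclone profiles")
    names = [str(i) for i in mean_profiles.index]
    if root_name in names:
        raise ValueError(f"subclone named {root_name!r} collides with the root")
    data = np.vstack([mean_profiles.to_numpy(), np.zeros(mean_profiles.shape[1])])
    ids = names + [root_name]
    if len(ids) == 2:
        d = float(np.linalg.norm(data[0] - data[1]))
        leaf = TreeNode(name=names[0], length=d)
        root = TreeNode(name=root_name, children=[leaf])
        return root
    dm = DistanceMatrix(squareform(pdist(data)), ids=ids)
    tree = nj(dm)
    root_tip = tree.find(root_name)
    rooted = tree.root_at(root_tip.parent)
    return rooted
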