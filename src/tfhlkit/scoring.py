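"""Per-cell gene-set scoring, cell-cycle phase assignment, and the
rank-sum differential-expression engine.

The signature score is a bounded mean-rank statistic: within each cell all N
genes are ranked by expression (ties get average ranks) and the score is

    (mean rank of set genes - (N + 1) / 2) / ((N - 1) / 2)

so a set at the top of the cell's expression ranking scores near +1, at the
bottom near -1, and a random set near 0. Being rank-based it is invariant to
any strictly monotone transform of a cell's expression vector, which makes
normalization immaterial to it. It is an order-preserving single-cell
stand-in for kernel-based per-sample enrichment scores; downstream group
comparisons depend only on score order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from .io import CountMatrix
from .stats import rank_sum_test, adjust_pvalues, signed_rank_test

__all__ = [
    "GeneSet",
    "read_gmt",
    "write_gmt",
    "signature_score",
    "cell_cycle_phase",
    "wilcoxon_deg",
    "compare_cluster_scores",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: tuple

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate members")


def read_gmt(path) -> list:
    """Read GMT (name <tab> description <tab> genes...)."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets.append(GeneSet(parts[0], tuple(dict.fromkeys(g for g in parts[2:] if g))))
    return sets


def write_gmt(sets, path) -> None:
    lines = ["\t".join([s.name, "."] + list(s.genes)) for s in sets]
    Path(path).write_text("\n".join(lines) + "\n")


def signature_score(counts: CountMatrix, gene_set: GeneSet) -> pd.Series:
    """Bounded mean-rank enrichment score per cell, indexed by barcode."""
    present = [g for g in gene_set.genes if g in set(counts.genes)]
    if not present:
        raise ValueError(f"no genes of set {gene_set.name!r} present in the matrix")
    dense = counts.dense().astype(float)
    n = counts.n_genes
    ranks = scipy.stats.rankdata(dense, axis=0)  # per cell (column) over genes
    gidx = counts.gene_index().get_indexer(present)
    mean_rank = ranks[gidx, :].mean(axis=0)
    score = (mean_rank - (n + 1) / 2.0) / ((n - 1) / 2.0)
    return pd.Series(score, index=counts.barcode_index(), name=gene_set.name)


def cell_cycle_phase(counts: CountMatrix, s_set: GeneSet, g2m_set: GeneSet) -> pd.DataFrame:
    """Assign G1/S/G2M per cell from S and G2M signature scores.

    A cell is G1 when both scores are <= 0; otherwise the phase with the
    larger positive score wins, ties going to S.
    """
    overlap = set(s_set.genes) & set(g2m_set.genes)
    if overlap:
        warnings.warn(f"genes in both cycle sets (kept in both): {sorted(overlap)[:5]}")
    s_score = signature_score(counts, s_set)
    g2m_score = signature_score(counts, g2m_set)
    phase = np.where(
        (s_score <= 0) & (g2m_score <= 0),
        "G1",
        np.where(s_score >= g2m_score, "S", "G2M"),
    )
    return pd.DataFrame({"phase": phase, "s_score": s_score, "g2m_score": g2m_score},
                        index=counts.barcode_index())


def wilcoxon_deg(
    counts: CountMatrix,
    group_a,
    group_b,
    correction: str = "bonferroni",
    min_cells: int = 3,
) -> pd.DataFrame:
    """Per-gene two-sided rank-sum differential expression, A vs B.

    Values are log2(CP10K + 1); log2FC is the difference of group means in
    that space. Genes expressed (count > 0) in fewer than ``min_cells`` cells
    of the pooled groups are not tested; the correction spans all tested
    genes. Returns a DataFrame with gene, log2fc, p, p_adj, direction.
    """
    group_a = list(group_a)
    group_b = list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("each group needs at least 3 cells")
    sub = counts.subset_cells(group_a + group_b)
    logm = sub.log_cp10k()
    na = len(group_a)
    expressed = (sub.dense() > 0).sum(axis=1)
    test_idx = np.flatnonzero(expressed >= min_cells)
    rows = []
    for gi in test_idx:
        a = logm[gi, :na]
        b = logm[gi, na:]
        _, p = rank_sum_test(a, b)
        lfc = float(a.mean() - b.mean())
        rows.append((sub.genes[gi], lfc, p))
    out = pd.DataFrame(rows, columns=["gene", "log2fc", "p"])
    out["p_adj"] = adjust_pvalues(out["p"].to_numpy(), method=correction)
    out["direction"] = np.where(out["log2fc"] > 0, "up", np.where(out["log2fc"] < 0, "down", "none"))
    return out


def compare_cluster_scores(scores: pd.Series, clusters: pd.Series, min_cells: int = 3) -> pd.DataFrame:
    """Per-cluster signed-rank test of signature scores against the pooled
    mean score, Benjamini-Hochberg adjusted across clusters.

    Clusters with fewer than ``min_cells`` cells are excluded with a warning.
    """
    clusters = clusters.reindex(scores.index)
    names = sorted(clusters.dropna().unique())
    if len(names) < 2:
        raise ValueError("need at least two clusters")
    pooled_mean = float(scores.mean())
    rows = []
    for name in names:
        vals = scores[clusters == name]
        if len(vals) < min_cells:
            warnings.warn(f"cluster {name!r} has fewer than {min_cells} cells; excluded")
            continue
        p = signed_rank_test(vals.to_numpy(), center=pooled_mean)
        rows.append((name, len(vals), float(vals.mean()), p))
    out = pd.DataFrame(rows, columns=["cluster", "n_cells", "mean_score", "p"])
    out["p_adj"] = adjust_pvalues(out["p"].to_numpy(), method="BH")
    return out
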