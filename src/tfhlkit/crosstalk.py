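"""Ligand-receptor crosstalk scoring between annotated clusters.

The score for a pair (ligand in sender cluster, receptor in receiver
cluster) is the mean of the two sides' cluster-mean log expression, with
multi-gene complexes valued at their weakest member (minimum rule). A pair
is only scored when each side is expressed in at least ``min_expr_fraction``
of its cluster's cells. Significance comes from shuffling cluster labels
across cells and recomputing the score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CountMatrix

__all__ = [
    "LRPair",
    "BUILTIN_LR_PAIRS",
    "read_lr_pairs",
    "lr_mean_score",
    "lr_permutation_p",
]


@dataclass(frozen=True)
class LRPair:
    pair_id: str
    ligand_genes: tuple
    receptor_genes: tuple

    def __post_init__(self):
        if not self.ligand_genes or not self.receptor_genes:
            raise ValueError(f"pair {self.pair_id}: empty gene list")


#: interactions featured in TFHL crosstalk narratives; real analyses should
#: supply a curated list via read_lr_pairs.
BUILTIN_LR_PAIRS = (
    LRPair("IL21_IL21R", ("IL21",), ("IL21R",)),
    LRPair("TNF_TNFRSF1A", ("TNF",), ("TNFRSF1A",)),
    LRPair("TGFB1_TGFBR1_TGFBR2", ("TGFB1",), ("TGFBR1", "TGFBR2")),
    LRPair("CD80_CD28", ("CD80",), ("CD28",)),
    LRPair("CD86_CTLA4", ("CD86",), ("CTLA4",)),
    LRPair("CD40LG_CD40", ("CD40LG",), ("CD40",)),
)


def read_lr_pairs(path) -> list:
    """TSV with columns pair_id, ligand_genes, receptor_genes (comma-joined
    complex members)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("pair_id", "ligand_genes", "receptor_genes") if c not in df.columns]
    if missing:
        raise ValueError(f"LR pair table missing columns: {missing}")
    return [
        LRPair(r.pair_id,
               tuple(g for g in r.ligand_genes.split(",") if g),
               tuple(g for g in r.receptor_genes.split(",") if g))
        for r in df.itertuples()
    ]


def _side_values(logm, dense, gene_index, genes, mask):
    """(complex expression value, expressed fraction) for one cluster side."""
    idx = gene_index.get_indexer(list(genes))
    if np.any(idx < 0):
        missing = [g for g, i in zip(genes, idx) if i < 0]
        raise KeyError(f"genes absent from matrix: {missing}")
    means = logm[idx][:, mask].mean(axis=1)
    fracs = (dense[idx][:, mask] > 0).mean(axis=1)
    # complex value and expressed fraction are both min over members
    return float(means.min()), float(fracs.min())


def lr_mean_score(
    counts: CountMatrix,
    labels: pd.Series,
    pair: LRPair,
    sender: str,
    receiver: str,
    min_expr_fraction: float = 0.1,
) -> float | None:
    """Crosstalk score, or None when either side fails the expression filter."""
    labels = labels.reindex(counts.barcode_index())
    for name in (sender, receiver):
        if not (labels == name).any():
            raise KeyError(f"unknown or empty cluster {name!r}")
    logm = counts.log_cp10k()
    dense = counts.dense()
    gidx = counts.gene_index()
    lig, lig_frac = _side_values(logm, dense, gidx, pair.ligand_genes,
                                 (labels == sender).to_numpy())
    rec, rec_frac = _side_values(logm, dense, gidx, pair.receptor_genes,
                                 (labels == receiver).to_numpy())
    if lig_frac < min_expr_fraction or rec_frac < min_expr_fraction:
        return None
    return (lig + rec) / 2.0


def lr_permutation_p(
    counts: CountMatrix,
    labels: pd.Series,
    pair: LRPair,
    sender: str,
    receiver: str,
    n_perm: int = 1000,
    seed: int = 0,
    min_expr_fraction: float = 0.1,
) -> tuple[float, float]:
    """(observed score, empirical p) under cluster-label shuffling.

    p = (1 + #{null >= observed}) / (n_perm + 1). The expression filter
    applies to the observed configuration only; null scores are computed
    unfiltered so the null is well defined.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low for stable empirical p-values")
    observed = lr_mean_score(counts, labels, pair, sender, receiver, min_expr_fraction)
    if observed is None:
        raise ValueError(f"pair {pair.pair_id} filtered by the expression rule")
    labels = labels.reindex(counts.barcode_index())
    logm = counts.log_cp10k()
    gidx = counts.gene_index()
    lig_idx = gidx.get_indexer(list(pair.ligand_genes))
    rec_idx = gidx.get_indexer(list(pair.receptor_genes))
    send_mask = (labels == sender).to_numpy()
    recv_mask = (labels == receiver).to_numpy()
    rng = np.random.default_rng(seed)
    n = counts.n_cells
    null = np.empty(n_perm)
    n_send = int(send_mask.sum())
    n_recv = int(recv_mask.sum())
    same_cluster = sender == receiver
    for i in range(n_perm):
        # shuffling labels jointly == drawing disjoint random subsets of the
        # original cluster sizes
        perm = rng.permutation(n)
        s_cells = perm[:n_send]
        r_cells = s_cells if same_cluster else perm[n_send: n_send + n_recv]
        lig_v = logm[lig_idx][:, s_cells].mean(axis=1).min()
        rec_v = logm[rec_idx][:, r_cells].mean(axis=1).min()
        null[i] = (lig_v + rec_v) / 2.0
    p = (1 + int((null >= observed - 1e-12).sum())) / (n_perm + 1)
    return observed, p
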