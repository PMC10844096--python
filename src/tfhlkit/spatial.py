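"""Spatial neighborhood interaction analysis for segmented imaging data.

For each image, cells become nodes of a neighbor graph (radius rule by
default, roughly one cell diameter); the interaction statistic for an ordered
type pair (A, B) is the mean number of type-B neighbors per type-A cell. Its
null distribution comes from shuffling all cell-type labels jointly within
the image, which preserves both the graph and the type abundances. Higher
z-scores mean the two types sit closer than chance (interaction), lower
z-scores mean they are farther apart (avoidance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import cKDTree

__all__ = [
    "NeighborGraph",
    "InteractionResult",
    "build_neighbor_graph",
    "interaction_score",
    "all_pairs_interactions",
    "summarize_across_images",
]


@dataclass
class NeighborGraph:
    """Per-image adjacency over segmented cells."""

    image_id: str
    adjacency: sp.csr_matrix  # symmetric, no self-edges
    cell_types: np.ndarray
    rule: str
    param: float


@dataclass
class InteractionResult:
    image_id: str
    type_a: str
    type_b: str
    observed: float
    null_mean: float
    null_sd: float
    z: float
    p_attraction: float
    p_avoidance: float
    classification: str  # interaction | avoidance | none
    degenerate: bool = False


def build_neighbor_graph(cells: pd.DataFrame, rule: str = "radius", param: float = 15.0) -> list:
    """Build one :class:`NeighborGraph` per image.

    ``radius``: undirected edge when Euclidean distance <= param (µm).
    ``knn``: directed k-nearest edges, symmetrized.
    """
    if rule == "radius" and param <= 0:
        raise ValueError("radius must be positive")
    if rule == "knn" and int(param) < 1:
        raise ValueError("k must be >= 1")
    graphs = []
    for image_id, img in cells.groupby("image_id", sort=True):
        xy = img[["x_um", "y_um"]].to_numpy()
        n = len(img)
        if n < 2:
            raise ValueError(f"image {image_id} has fewer than 2 cells")
        if rule == "radius":
            tree = cKDTree(xy)
            pairs = tree.query_pairs(param, output_type="ndarray")
            rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
            cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
        elif rule == "knn":
            k = min(int(param), n - 1)
            tree = cKDTree(xy)
            _, idx = tree.query(xy, k=k + 1)
            src = np.repeat(np.arange(n), k)
            dst = idx[:, 1:].ravel()
            rows = np.concatenate([src, dst])
            cols = np.concatenate([dst, src])
        else:
            raise ValueError(f"unknown neighbor rule {rule!r}")
        adj = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        adj.data[:] = 1.0  # symmetrized, binary
        adj.setdiag(0)
        adj.eliminate_zeros()
        graphs.append(NeighborGraph(
            image_id=str(image_id),
            adjacency=adj,
            cell_types=img["cell_type"].to_numpy(),
            rule=rule,
            param=param,
        ))
    return graphs


def interaction_score(
    graph: NeighborGraph,
    type_a: str,
    type_b: str,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.01,
) -> InteractionResult:
    """Permutation interaction/avoidance test for one ordered type pair.

    Empirical p-values use the add-one convention
    ``p = (1 + #{null >= obs}) / (n_perm + 1)`` (and <= for avoidance), which
    keeps them valid at any permutation count.
    """
    rng = np.random.default_rng(seed)
    labels = graph.cell_types
    ind_a = labels == type_a
    ind_b = labels == type_b
    n_a = int(ind_a.sum())
    if n_a == 0 or ind_b.sum() == 0:
        raise ValueError(f"image {graph.image_id}: no cells of type {type_a!r} or {type_b!r}")
    adj = graph.adjacency

    def stat(a_mask, b_mask):
        return float(a_mask @ (adj @ b_mask.astype(float))) / a_mask.sum()

    observed = stat(ind_a, ind_b)
    null = np.empty(n_perm)
    n = len(labels)
    for i in range(n_perm):
        perm = rng.permutation(n)
        null[i] = stat(ind_a[perm], ind_b[perm])
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=0))
    p_att = (1 + int((null >= observed - 1e-12).sum())) / (n_perm + 1)
    p_avo = (1 + int((null <= observed + 1e-12).sum())) / (n_perm + 1)
    if null_sd == 0:
        return InteractionResult(graph.image_id, type_a, type_b, observed, null_mean, 0.0,
                                 float("nan"), p_att, p_avo, "none", degenerate=True)
    z = (observed - null_mean) / null_sd
    if p_att <= alpha:
        classification = "interaction"
    elif p_avo <= alpha:
        classification = "avoidance"
    else:
        classification = "none"
    return InteractionResult(graph.image_id, type_a, type_b, observed, null_mean, null_sd,
                             z, p_att, p_avo, classification)


def all_pairs_interactions(graphs, n_perm: int = 1000, seed: int = 0, alpha: float = 0.01) -> list:
    """Interaction results for every ordered type pair in every image."""
    results = []
    for gi, graph in enumerate(graphs):
        types = sorted(set(graph.cell_types))
        for ai, a in enumerate(types):
            for bi, b in enumerate(types):
                results.append(interaction_score(
                    graph, a, b, n_perm=n_perm,
                    seed=seed + 1009 * gi + 31 * ai + bi, alpha=alpha,
                ))
    return results


def summarize_across_images(results) -> pd.DataFrame:
    """Type-pair matrix across images: mean z and fraction of images
    significant in each direction."""
    if not results:
        raise ValueError("no results to summarize")
    df = pd.DataFrame([{
        "type_a": r.type_a, "type_b": r.type_b, "z": r.z,
        "interaction": r.classification == "interaction",
        "avoidance": r.classification == "avoidance",
    } for r in results])
    out = df.groupby(["type_a", "type_b"], sort=True).agg(
        mean_z=("z", "mean"),
        frac_interaction=("interaction", "mean"),
        frac_avoidance=("avoidance", "mean"),
        n_images=("z", "size"),
    ).reset_index()
    return out
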