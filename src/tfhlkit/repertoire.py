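"""Clonotype assembly, chain-configuration classes, tumor-clone calling, and
repertoire overlap.

A clonotype is the exact nucleotide identity of a cell's productive chain
set: the canonical key is the sorted tuple of (chain, V gene, J gene, CDR3
nucleotide sequence), so two cells share a clonotype only when every retained
productive chain matches at nucleotide resolution. This chain-level
resolution is what lets two tumor clones share an identical TRB chain while
differing in TRA, the hallmark used to group related clones into one tumor
clone group.

Chain-configuration classes: ``paired`` (one productive TRA + one TRB),
``single_alpha`` / ``single_beta`` (only one chain, the single-chain TCR
phenotype of TFHL tumor cells), and ``multi`` (more than one retained chain at
a locus). B cells run through the same machinery with IGH as the heavy locus
and IGK/IGL as the light locus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "assemble_clonotypes",
    "clone_sizes",
    "call_tumor_clones",
    "repertoire_overlap",
    "cross_compartment_sharing",
    "TumorCallResult",
]

_ALPHA_LIKE = {"TRA", "IGK", "IGL"}
_BETA_LIKE = {"TRB", "IGH"}


def _canonical_key(chains) -> str:
    return ";".join("|".join(c) for c in sorted(chains))


def assemble_clonotypes(contigs: pd.DataFrame) -> pd.DataFrame:
    """Assign each cell a clonotype key and chain-configuration class.

    Only productive contigs are used. Within a cell and chain locus,
    duplicate records are merged (UMIs summed) and only records tied at the
    highest UMI count are retained, ordered by CDR3 for determinism; a locus
    that keeps more than one distinct chain after this tie-break makes the
    cell ``multi``. Cells with no productive chains are unassigned (absent
    from the output).

    Returns a DataFrame indexed by barcode with columns ``key``,
    ``chain_config``, ``n_chains``, ``trb_cdr3`` (';'-joined beta-locus CDR3
    nucleotide strings, used for related-clone grouping).
    """
    prod = contigs[contigs["productive"].astype(bool)].copy()
    if prod.empty:
        return pd.DataFrame(columns=["key", "chain_config", "n_chains", "trb_cdr3"])
    merged = (
        prod.groupby(["barcode", "chain", "v_gene", "j_gene", "cdr3_nt"], sort=False)["umis"]
        .sum()
        .reset_index()
    )
    records = []
    for barcode, cell in merged.groupby("barcode", sort=False):
        retained = []
        multi = False
        for chain_name, locus in cell.groupby("chain", sort=True):
            top = locus[locus["umis"] == locus["umis"].max()]
            top = top.sort_values("cdr3_nt")
            if len(top) > 1:
                multi = True
            for _, row in top.iterrows():
                retained.append((row["chain"], row["v_gene"], row["j_gene"], row["cdr3_nt"]))
        chains = sorted(retained)
        alpha = [c for c in chains if c[0] in _ALPHA_LIKE]
        beta = [c for c in chains if c[0] in _BETA_LIKE]
        if multi or len(alpha) > 1 or len(beta) > 1:
            config = "multi"
        elif alpha and beta:
            config = "paired"
        elif beta:
            config = "single_beta"
        else:
            config = "single_alpha"
        records.append((
            barcode,
            _canonical_key(chains),
            config,
            len(chains),
            ";".join(sorted(c[3] for c in beta)),
        ))
    out = pd.DataFrame(records, columns=["barcode", "key", "chain_config", "n_chains", "trb_cdr3"])
    return out.set_index("barcode")


def clone_sizes(assignments: pd.DataFrame) -> pd.Series:
    """Cells per clonotype key (clone size), descending."""
    if assignments.empty:
        raise ValueError("no clonotype assignments")
    return assignments["key"].value_counts()


@dataclass
class TumorCallResult:
    """Result of clonality-based tumor calling for one sample."""

    clonotype_labels: pd.Series  # key -> {major, minor, none}
    cell_is_tumor: pd.Series  # barcode -> bool
    tumor_fraction: float
    related_groups: list = field(default_factory=list)  # lists of keys sharing a TRB

    @property
    def major_keys(self) -> list:
        return sorted(self.clonotype_labels.index[self.clonotype_labels == "major"])


def call_tumor_clones(
    assignments: pd.DataFrame,
    min_major_fraction: float = 0.05,
    min_minor_fraction: float = 0.01,
) -> TumorCallResult:
    """Call major/minor tumor clonotypes by clonal fraction.

    Clonotypes at or above ``min_major_fraction`` of assigned cells are major
    candidates; candidates sharing an identical TRB CDR3 nucleotide sequence
    are merged into one related-clone tumor group and the group with the
    largest total fraction is the (single) major group. Clonotypes in
    [min_minor_fraction, min_major_fraction) that share a TRB with the major
    group are minor. All cells of major or minor clonotypes are tumor.
    """
    if assignments.empty:
        warnings.warn("no clonotype assignments; empty tumor call")
        return TumorCallResult(
            clonotype_labels=pd.Series(dtype=object),
            cell_is_tumor=pd.Series(dtype=bool),
            tumor_fraction=0.0,
        )
    sizes = clone_sizes(assignments)
    n = int(sizes.sum())
    fractions = sizes / n
    trb_of = assignments.drop_duplicates("key").set_index("key")["trb_cdr3"]

    def trb_set(key):
        s = trb_of.get(key, "")
        return set(s.split(";")) - {""} if isinstance(s, str) else set()

    candidates = sorted(fractions.index[fractions >= min_major_fraction])
    labels = pd.Series("none", index=fractions.index, dtype=object)
    related_groups: list = []
    if candidates:
        # union-find over candidates sharing any TRB CDR3
        parent = {k: k for k in candidates}

        def find(k):
            while parent[k] != k:
                parent[k] = parent[parent[k]]
                k = parent[k]
            return k

        for i, a in enumerate(candidates):
            for b in candidates[i + 1:]:
                if trb_set(a) & trb_set(b):
                    parent[find(a)] = find(b)
        groups: dict = {}
        for k in candidates:
            groups.setdefault(find(k), []).append(k)
        ranked = sorted(
            groups.values(),
            key=lambda g: (-float(fractions[g].sum()), min(g)),
        )
        major_group = ranked[0]
        labels[major_group] = "major"
        # other expanded candidates are flagged as minor, keeping one major
        # clone group per sample
        for g in ranked[1:]:
            labels[g] = "minor"
        major_trbs = set().union(*(trb_set(k) for k in major_group))
        minor_mask = (fractions >= min_minor_fraction) & (fractions < min_major_fraction)
        for key in fractions.index[minor_mask]:
            if trb_set(key) & major_trbs:
                labels[key] = "minor"
        related_groups = [sorted(g) for g in groups.values()]

    cell_is_tumor = assignments["key"].map(labels).ne("none")
    tumor_fraction = float(cell_is_tumor.mean())
    return TumorCallResult(
        clonotype_labels=labels,
        cell_is_tumor=cell_is_tumor,
        tumor_fraction=tumor_fraction,
        related_groups=related_groups,
    )


def _freqs(assignments: pd.DataFrame) -> pd.Series:
    sizes = clone_sizes(assignments)
    return sizes / sizes.sum()


def repertoire_overlap(group_a: pd.DataFrame, group_b: pd.DataFrame, method: str = "morisita") -> float:
    """Clonal sharing between two cell groups.

    ``public``: number of shared clonotype keys. ``jaccard``: |A∩B|/|A∪B| on
    key sets. ``morisita``: Morisita-Horn index on clone frequency vectors,
    in [0, 1].
    """
    if group_a.empty or group_b.empty:
        raise ValueError("both groups must be nonempty")
    keys_a = set(group_a["key"])
    keys_b = set(group_b["key"])
    if method == "public":
        return float(len(keys_a & keys_b))
    if method == "jaccard":
        return len(keys_a & keys_b) / len(keys_a | keys_b)
    if method == "morisita":
        p = _freqs(group_a)
        q = _freqs(group_b)
        shared = p.index.intersection(q.index)
        num = 2.0 * float((p[shared] * q[shared]).sum())
        den = float((p**2).sum() + (q**2).sum())
        return num / den
    raise ValueError(f"unknown overlap method: {method!r}")


def cross_compartment_sharing(assignments_ln: pd.DataFrame, assignments_pb: pd.DataFrame) -> pd.DataFrame:
    """Clonotypes present in both compartments with their clone sizes."""
    sizes_ln = clone_sizes(assignments_ln)
    sizes_pb = clone_sizes(assignments_pb)
    shared = sorted(sizes_ln.index.intersection(sizes_pb.index))
    return pd.DataFrame({
        "key": shared,
        "size_LN": sizes_ln[shared].to_numpy(dtype=int),
        "size_PB": sizes_pb[shared].to_numpy(dtype=int),
    })
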