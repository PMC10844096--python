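"""Tumor-specific marker discovery cascade.

Per sample, genes up-regulated in tumor cells are found against two
backgrounds: all non-malignant mononuclear cells (MNCs), and — for lymph-node
samples — normal T follicular helper cells. Genes significant in at least
``min_samples`` samples per compartment form the LN and PB candidate sets;
the final candidates are their intersection, optionally restricted to genes
expressed in under 10% of pooled non-malignant cells (a reproducible
specificity rule standing in for manual embedding inspection).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix
from .scoring import wilcoxon_deg

__all__ = [
    "SampleInput",
    "per_sample_tumor_deg",
    "recurrence_filter",
    "intersect_compartments",
    "find_tumor_markers",
]


@dataclass
class SampleInput:
    """One sample's matrix with per-cell tumor / normal-TFH flags."""

    sample_id: str
    compartment: str  # LN | PB
    counts: CountMatrix
    tumor_barcodes: list
    mnc_barcodes: list  # non-malignant background cells
    normal_tfh_barcodes: list = field(default_factory=list)


def per_sample_tumor_deg(
    sample: SampleInput,
    alpha: float = 0.05,
    min_log2fc: float = 0.25,
    min_cells: int = 20,
) -> dict:
    """Up-regulated gene sets for one sample vs each background.

    Returns {'vs_mnc': set, 'vs_tfh': set or None}; the TFH comparison is
    None (with a warning) when the sample lacks normal-TFH cells.
    """
    if len(sample.tumor_barcodes) < min_cells or len(sample.mnc_barcodes) < min_cells:
        raise ValueError(
            f"sample {sample.sample_id}: needs >= {min_cells} tumor and background cells"
        )

    def up_genes(background):
        deg = wilcoxon_deg(sample.counts, sample.tumor_barcodes, background,
                           correction="bonferroni")
        hits = deg[(deg["p_adj"] < alpha) & (deg["log2fc"] > min_log2fc)]
        return set(hits["gene"])

    vs_mnc = up_genes(sample.mnc_barcodes)
    vs_tfh = None
    if sample.compartment == "LN":
        if len(sample.normal_tfh_barcodes) >= min_cells:
            vs_tfh = up_genes(sample.normal_tfh_barcodes)
        else:
            warnings.warn(f"sample {sample.sample_id}: no normal-TFH background; vs-TFH list empty")
            vs_tfh = set()
    return {"vs_mnc": vs_mnc, "vs_tfh": vs_tfh}


def recurrence_filter(per_sample: dict, compartment: str, min_samples: int = 2) -> set:
    """Candidate genes recurrent across samples of one compartment.

    ``per_sample`` maps sample id -> output of :func:`per_sample_tumor_deg`.
    A gene is kept when significant vs the MNC background in at least
    ``min_samples`` samples and, for LN, also vs normal TFH in at least
    ``min_samples`` LN samples.
    """
    if len(per_sample) < min_samples:
        raise ValueError(f"need at least {min_samples} samples, got {len(per_sample)}")
    mnc_counts: dict = {}
    tfh_counts: dict = {}
    for res in per_sample.values():
        for g in res["vs_mnc"]:
            mnc_counts[g] = mnc_counts.get(g, 0) + 1
        if res.get("vs_tfh") is not None:
            for g in res["vs_tfh"]:
                tfh_counts[g] = tfh_counts.get(g, 0) + 1
    kept = {g for g, c in mnc_counts.items() if c >= min_samples}
    if compartment == "LN":
        kept &= {g for g, c in tfh_counts.items() if c >= min_samples}
    return kept


def intersect_compartments(ln_set: set, pb_set: set, recurrence: dict | None = None) -> pd.DataFrame:
    """Final candidates = LN ∩ PB, sorted by combined recurrence then gene."""
    final = ln_set & pb_set
    recurrence = recurrence or {}
    rows = sorted(final, key=lambda g: (-recurrence.get(g, 0), g))
    return pd.DataFrame({
        "gene": rows,
        "combined_recurrence": [recurrence.get(g, 0) for g in rows],
        "in_LN_list": True,
        "in_PB_list": True,
        "final_candidate": True,
    })


def find_tumor_markers(
    samples,
    min_samples: int = 2,
    alpha: float = 0.05,
    min_log2fc: float = 0.25,
    min_cells: int = 20,
    max_background_fraction: float = 0.10,
) -> pd.DataFrame:
    """Run the full cascade over a list of :class:`SampleInput`.

    ``max_background_fraction`` applies the specificity rule: candidates must
    be expressed in fewer than that fraction of non-malignant cells pooled
    across samples (set to 1 to disable).
    """
    per_sample = {
        s.sample_id: per_sample_tumor_deg(s, alpha=alpha, min_log2fc=min_log2fc, min_cells=min_cells)
        for s in samples
    }
    by_comp: dict = {"LN": {}, "PB": {}}
    for s in samples:
        by_comp[s.compartment][s.sample_id] = per_sample[s.sample_id]
    ln_set = recurrence_filter(by_comp["LN"], "LN", min_samples) if len(by_comp["LN"]) >= min_samples else set()
    pb_set = recurrence_filter(by_comp["PB"], "PB", min_samples) if len(by_comp["PB"]) >= min_samples else set()

    recurrence = {}
    for res in per_sample.values():
        for g in res["vs_mnc"]:
            recurrence[g] = recurrence.get(g, 0) + 1
    out = intersect_compartments(ln_set, pb_set, recurrence)

    if max_background_fraction < 1.0 and not out.empty:
        fracs = _pooled_background_fraction(samples, out["gene"].tolist())
        out = out[out["gene"].map(fracs) < max_background_fraction].reset_index(drop=True)
    return out


def _pooled_background_fraction(samples, genes) -> dict:
    expressed = {g: 0 for g in genes}
    total = 0
    for s in samples:
        background = list(s.mnc_barcodes) + list(s.normal_tfh_barcodes)
        sub = s.counts.subset_cells(background)
        dense = sub.dense()
        idx = sub.gene_index().get_indexer(genes)
        for g, gi in zip(genes, idx):
            if gi >= 0:
                expressed[g] += int((dense[gi] > 0).sum())
        total += len(background)
    return {g: expressed[g] / total for g in genes}
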