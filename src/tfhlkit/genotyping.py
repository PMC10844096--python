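"""Per-cell somatic-mutation genotyping from read pileups.

Because allelic dropout is pervasive in scRNA-seq, absence of mutant reads is
not evidence of wild type: in a patient whose bulk exome carries the
mutation, a cell is MUT when at least one alternate read is seen and
``unknown`` otherwise (covered without mutant reads, or no coverage at all).
Cells from patients whose exome lacks the mutation are WT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import rank_sum_test, adjust_pvalues

__all__ = [
    "Locus",
    "filter_loci",
    "call_genotypes",
    "genotype_fraction_summary",
    "genotype_score_association",
]

MUTANT_BY_WES = "mutant_by_WES"
ABSENT_BY_WES = "absent_by_WES"


@dataclass(frozen=True)
class Locus:
    """A genotyped locus, e.g. ``RHOA_G17V``, with its patient-level bulk
    WES status."""

    locus_id: str
    patient_status: str  # mutant_by_WES | absent_by_WES

    def __post_init__(self):
        if self.patient_status not in (MUTANT_BY_WES, ABSENT_BY_WES):
            raise ValueError(f"unknown patient status {self.patient_status!r}")


def filter_loci(
    pileups: pd.DataFrame,
    min_total_coverage: int = 100,
    min_mut_cells: int = 20,
    strict_cell_count: bool = True,
) -> list:
    """Retain loci with aggregate coverage >= ``min_total_coverage`` and more
    than ``min_mut_cells`` cells showing at least one alternate read.

    ``strict_cell_count=True`` reads the cell-count rule strictly (> rather
    than >=); set False for the inclusive reading.
    """
    grouped = pileups.groupby("locus")
    total_cov = grouped["total"].sum()
    mut_cells = grouped.apply(lambda g: int((g["alt_reads"] >= 1).sum()), include_groups=False)
    keep = total_cov >= min_total_coverage
    if strict_cell_count:
        keep &= mut_cells > min_mut_cells
    else:
        keep &= mut_cells >= min_mut_cells
    return sorted(total_cov.index[keep])


def call_genotypes(pileups: pd.DataFrame, locus: Locus, min_alt_reads: int = 1) -> pd.DataFrame:
    """Per-cell genotype calls at one locus.

    Cells of an ``absent_by_WES`` patient are WT. Otherwise a cell is MUT
    with >= ``min_alt_reads`` alternate reads, else ``unknown`` (no mutant
    reads or no coverage).
    """
    sub = pileups[pileups["locus"] == locus.locus_id]
    if (sub[["ref_reads", "alt_reads"]] < 0).any().any():
        raise ValueError("negative read counts")
    if locus.patient_status == ABSENT_BY_WES:
        status = np.full(len(sub), "WT", dtype=object)
    else:
        status = np.where(sub["alt_reads"] >= min_alt_reads, "MUT", "unknown")
    return pd.DataFrame({
        "barcode": sub["barcode"].to_numpy(),
        "locus": locus.locus_id,
        "status": status,
        "alt_reads": sub["alt_reads"].to_numpy(),
        "total": sub["total"].to_numpy(),
    })


def genotype_fraction_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-locus fractions of MUT, covered-without-mutant-reads, and
    no-coverage cells (mutant-patient calls only; the three sum to 1)."""
    if calls.empty:
        raise ValueError("empty call set")
    if (calls["status"] == "WT").any():
        raise ValueError("summary is defined over mutant-patient cells only")
    rows = []
    for locus, grp in calls.groupby("locus"):
        n = len(grp)
        mut = float((grp["status"] == "MUT").mean())
        no_cov = float(((grp["status"] == "unknown") & (grp["total"] == 0)).mean())
        no_alt = float(((grp["status"] == "unknown") & (grp["total"] > 0)).mean())
        rows.append((locus, n, mut, no_alt, no_cov))
    return pd.DataFrame(rows, columns=["locus", "n_cells", "frac_mut", "frac_no_mutant_read", "frac_no_coverage"])


def genotype_score_association(calls: pd.DataFrame, scores: pd.Series) -> tuple[float, float, float]:
    """Compare a per-cell score between MUT and WT cells (unknown excluded).

    Returns (rank-sum statistic, two-sided p, Bonferroni-adjusted p for the
    single comparison, i.e. identical here but kept for interface symmetry
    with multi-locus use).
    """
    merged = calls.set_index("barcode").join(scores.rename("score"), how="inner")
    mut = merged.loc[merged["status"] == "MUT", "score"].dropna()
    wt = merged.loc[merged["status"] == "WT", "score"].dropna()
    if mut.empty or wt.empty:
        raise ValueError("need at least one MUT and one WT cell with scores")
    stat, p = rank_sum_test(mut.to_numpy(), wt.to_numpy())
    p_adj = float(adjust_pvalues([p], method="bonferroni")[0])
    return stat, p, p_adj
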