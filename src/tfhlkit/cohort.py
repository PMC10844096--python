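"""Cohort-level recurrence summaries and cluster-proportion comparisons."""

from __future__ import annotations

import warnings
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .stats import rank_sum_test, adjust_pvalues

__all__ = [
    "percent_half_up",
    "recurrence_summary",
    "proportion_compare",
    "example_wes_cohort",
    "example_scrna_cnv_cohort",
]


def percent_half_up(count: int, total: int) -> float:
    """100*count/total, round-half-up to one decimal (reporting convention)."""
    if total < 1:
        raise ValueError("total must be >= 1")
    pct = Decimal(100 * count) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def recurrence_summary(table: pd.DataFrame, feature: str) -> tuple[int, int, float]:
    """(count, total, percent) of samples flagged for ``feature``.

    ``table`` holds one row per patient/sample with boolean feature columns.
    """
    if feature not in table.columns:
        raise KeyError(f"unknown feature {feature!r}")
    flags = table[feature].astype(bool)
    count = int(flags.sum())
    total = int(len(flags))
    return count, total, percent_half_up(count, total)


def proportion_compare(
    cellmeta: pd.DataFrame,
    group_a: str,
    group_b: str,
    non_malignant: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-cluster per-sample fractions with a rank-sum comparison between
    two clinical-status groups, BH-adjusted across clusters.

    Fractions are cluster cells / non-malignant cells per sample
    (``non_malignant`` is a barcode-indexed boolean mask; default all cells).
    Groups with fewer than two samples are skipped with a warning.
    """
    meta = cellmeta.copy()
    if non_malignant is not None:
        mask = non_malignant.reindex(meta["barcode"]).fillna(True).to_numpy()
        meta = meta[mask]
    frac = (
        meta.groupby(["sample", "status", "cluster"], sort=True).size()
        .unstack(fill_value=0)
    )
    frac = frac.div(frac.sum(axis=1), axis=0)
    frac.index.names = ["sample", "status"]
    statuses = frac.index.get_level_values("status")
    a = frac[statuses == group_a]
    b = frac[statuses == group_b]
    if len(a) < 2 or len(b) < 2:
        warnings.warn(f"fewer than 2 samples in {group_a!r} or {group_b!r}; comparison skipped")
        return pd.DataFrame(columns=["cluster", f"mean_{group_a}", f"mean_{group_b}", "p", "p_adj"])
    rows = []
    for cluster in frac.columns:
        _, p = rank_sum_test(a[cluster].to_numpy(), b[cluster].to_numpy())
        rows.append((cluster, float(a[cluster].mean()), float(b[cluster].mean()), p))
    out = pd.DataFrame(rows, columns=["cluster", f"mean_{group_a}", f"mean_{group_b}", "p"])
    out["p_adj"] = adjust_pvalues(out["p"].to_numpy(), method="BH")
    return out


def example_wes_cohort() -> pd.DataFrame:
    """A 14-patient bulk-WES cohort table with the recurrence structure of a
    typical TFHL series: TET2 in 11, RHOA G17V and DNMT3A in 6, IDH2 R172 in
    2, chr5 gain in 5, chr7/19/21/22q gains in 2, chr5+chr21 co-gain in 1."""
    n = 14
    t = lambda k: [True] * k + [False] * (n - k)  # noqa: E731
    df = pd.DataFrame({
        "patient": [f"P{i + 1:02d}" for i in range(n)],
        "TET2": t(11),
        "RHOA_G17V": t(6),
        "DNMT3A": t(6),
        "IDH2_R172": t(2),
        "chr5_gain": t(5),
        "chr7_gain": t(2),
        "chr19_gain": t(2),
        # chr21 gain in 2 patients, one of them co-carrying chr5 gain
        "chr21_gain": [True] + [False] * 12 + [True],
        "chr22q_gain": t(2),
        "source": "WES",
    })
    return df


def example_scrna_cnv_cohort() -> pd.DataFrame:
    """Nine LN samples with single-cell CNV calls; chr5 gain in 6 of 9."""
    n = 9
    return pd.DataFrame({
        "sample": [f"LN{i + 1}" for i in range(n)],
        "chr5_gain": [True] * 6 + [False] * 3,
        "source": "scRNA",
    })
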