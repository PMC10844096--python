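"""Infer copy number from expression, call chromosome gains, and build the
clone tree.

Genes are ordered by genomic position, expression is centered on the normal
T cells and smoothed along each chromosome; a chr5 x1.5 gain shifts smoothed
values by ~log2(1.5) = 0.585. The clone tree (neighbor joining, rooted at an
all-neutral profile) orders the accumulation of events.
"""

import pandas as pd

from tfhlkit import cnv, simulate as sim

config = sim.SimConfig(
    populations=(sim.PopulationSpec("tumor", 600, is_tumor=True),
                 sim.PopulationSpec("normal_T", 900)),
    # nested lineage: chr5 gain in half the tumor cells, chr21 gain in half
    # of those carriers
    cnv_events=(sim.CNVEvent("chr5", 1.5, 0.5, group="lineage"),
                sim.CNVEvent("chr21", 1.5, 0.25, group="lineage")),
    seed=3,
)
matrix, truth = sim.generate_expression(config)
reference = truth.cells.loc[~truth.cells["is_tumor"], "barcode"].tolist()

rel, genes, chroms = cnv.compute_relative_expression(matrix, config.gene_table(), reference)
profile = cnv.smooth_by_position(rel, genes, chroms, matrix.barcodes, window=101)
calls = cnv.call_chromosome_cnv(profile)

carriers = truth.cnv_carriers["chr5|1.5"]
chr5 = calls[calls["chrom"] == "chr5"].set_index("barcode")["state"]
print(f"chr5 gain sensitivity: {(chr5[carriers[carriers].index] == 'gain').mean():.3f}")
print(f"false-gain rate elsewhere: "
      f"{(calls[~calls['chrom'].isin(['chr5', 'chr21'])]['state'] == 'gain').mean():.3f}")

scores = cnv.cnv_score(profile)
tumor = truth.cells.set_index("barcode")["is_tumor"]
print(f"CNV score, chr5-gain cells: {scores[carriers[carriers].index].mean():.4f}")
print(f"CNV score, neutral tumor:   {scores[tumor.index[tumor & ~carriers]].mean():.4f}")

# subclone mean profiles from the planted lineage, then the clone tree
carriers21 = truth.cnv_carriers["chr21|1.5"]
groups = pd.Series("bulk", index=carriers.index)
groups[carriers & ~carriers21] = "chr5_gain"
groups[carriers & carriers21] = "chr5_chr21_gain"
idx = {b: i for i, b in enumerate(profile.barcodes)}
means = {name: profile.values[[idx[b] for b in g]].mean(axis=0)
         for name, g in groups[tumor].groupby(groups).groups.items()}
tree = cnv.build_clone_tree(pd.DataFrame(means).T)
print(tree.ascii_art())
# the chr5+chr21 subclone branches inside the chr5 lineage, not off the root
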