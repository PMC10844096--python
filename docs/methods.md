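# Methods

This note documents the models and procedures tfhlkit implements, the
defaults that matter, what the synthetic-data generator does and does not
emulate, and the design choices made where the design was genuinely open.

## Synthetic data model

`simulate.SimConfig` describes one sample. UMI counts are negative binomial
with mean

    mu(gene, cell) = baseline × program_FC × marker_FC × dosage

and a common dispersion θ (variance μ + μ²/θ; θ = ∞ gives the Poisson
limit). `program_FC` applies to a population's program genes, `marker_FC`
only to tumor cells at the configured marker genes, and `dosage` to genes on
a chromosome carrying a planted copy-number event in that cell. Marker genes
are tumor-restricted: their baseline is set to `marker_baseline` (default
0.05 expected UMIs) in every cell and multiplied by `marker_fc` (default 30)
in tumor cells, the expression pattern of a genuinely tumor-specific surface
marker.

The default gene universe is a miniature transcriptome: 10 chromosomes
(including those recurrently gained in TFHL — 5, 7, 19, 21, 22) × 150 genes,
baseline mean 5 UMIs per gene (≈7,500 UMIs per cell, a typical droplet
library). A real transcriptome spreads the same library over many more,
mostly dimmer genes; concentrating it preserves the *per-chromosome*
aggregate counts that position-smoothed CNV inference actually consumes,
while keeping simulations small. Consequences: per-gene statistics are less
sparse than real data, and no gene–gene correlation structure beyond the
planted programs exists. Passing tests therefore demonstrate correct
recovery of planted effects at realistic information content, not robustness
to dropout-heavy tails or co-expression confounders.

TCR contigs: each tumor clone has fixed TRA/TRB CDR3 nucleotide strings
(random 30–45-mers; V/J names from a small built-in list — only string
identity matters downstream). A `single_chain_fraction` of clone cells drops
one chain, alpha or beta with equal probability. Non-tumor cells get unique
clonotypes except configured expanded clones. Pileups: coverage is
Poisson(mean_coverage); a true-mutant cell yields alternate reads only when
its transcript is captured (Bernoulli(capture_prob)) and covered, so the
expected fraction of mutant cells with ≥1 alternate read is
`capture × (1 − e^(−mean_coverage))` — the closed form the tests check.
Spatial fields: background types are homogeneous Poisson; attraction pairs
follow a Neyman–Scott parent–offspring process (both types scattered within
`cluster_radius` of shared parents); avoidance pairs occupy opposite bands
separated by a quarter-field guard gap, which makes "zero cross-neighbors
below field/4" true by construction. Identical configs (seed included)
reproduce all outputs bit for bit; each generator draws from its own
deterministic substream.

## Clonotypes and tumor calling

A clonotype key is the sorted tuple of (chain, V, J, CDR3_nt) over retained
productive chains — nucleotide resolution, because related tumor clones are
recognized by an *identical* TRB chain with different TRA. Within a cell and
chain locus, exact duplicate contigs merge (UMIs summed); only contigs tied
at the top UMI count are retained, ordered lexically by CDR3 for
determinism. A locus retaining more than one distinct chain marks the cell
`multi` (e.g., two productive TRA alleles); such cells keep all chains in
the key and are included, flagged. B cells use the same machinery with IGH
as the heavy locus and IGK/IGL as light; exact-match clones only, no
somatic-hypermutation clustering.

Tumor calling is clonality-based with documented, configurable thresholds
(the convention of "major/minor by clonality" leaves the cutoffs open):
clonotypes at ≥5% of assigned cells are major candidates; candidates sharing
a TRB CDR3 merge into related-clone groups, and the group with the largest
total fraction is the sample's single major group. Clonotypes in [1%, 5%)
sharing a TRB with that group are minor. When several unrelated clonotypes
exceed 5% (as the TRA-only keys of single-chain cells do for large clones),
the non-winning candidates are labelled minor rather than creating a second
major group — one dominant clone per sample is an invariant. Limitation:
tumor cells that kept only their TRA chain cannot be linked to the group via
TRB and are missed when their key falls below the major threshold; this is
visible in the worked examples and is inherent to TRB-based linking.

Overlap measures: `public` (shared key count), Jaccard on key sets, and the
Morisita–Horn index `2·Σp_i·q_i / (Σp_i² + Σq_i²)` on clone frequencies.

## Genotyping

For a locus mutant in the patient's bulk exome, a cell is MUT with ≥1
alternate read (configurable `min_alt_reads`; no error model — presence/
absence is the convention for hotspot genotyping at these depths) and
`unknown` otherwise, covering both covered-without-mutant-reads and
no-coverage cells; allelic dropout makes absence of evidence uninformative.
Cells of patients without the mutation by exome are WT. Locus filters:
aggregate coverage ≥100 reads across the analyzed cell set (configurable
per-sample if desired) and strictly more than 20 cells with an alternate
read; "more than" is read strictly, with an inclusive switch, since either
reading of the convention is defensible.

## CNV inference

The standard expression-smoothing recipe: CP10K → log2(x+1) → per-gene
centering on a reference cell set (non-malignant cells by default; the
reference is configuration) → clip to ±1 → centered moving average of 101
genes within each chromosome, shrinking at edges (and shrunk with a warning
for chromosomes narrower than half the window) → per-cell median centering,
which removes cell-level offsets that would otherwise mimic whole-genome
dosage shifts. A dosage-d gain appears as a ≈log2(d) plateau (0.585 for
1.5×) minus a small compositional residual from library normalization.

Chromosome-level calls: gain when the fraction of the chromosome's windows
above +0.1 exceeds 0.5 (loss symmetric; ties → neutral, larger supporting
fraction wins otherwise). Whole-chromosome calls only — the recurrent TFHL
events are chromosome-scale; sub-chromosomal segmentation (HMMs) is out of
scope. The per-cell CNV score is the mean squared smoothed value, a
non-negative aberrance scalar that is zero iff the profile is exactly
neutral and strictly increases when any window's magnitude grows; the
precise published formulation of such scores varies, and mean-of-squares is
used here as a documented stand-in. Subclones come from Ward-linkage
hierarchical clustering of smoothed profiles; the clone tree is neighbor
joining (scikit-bio) on Euclidean distances among subclone mean profiles
plus an appended all-zero profile, rooted at that neutral node so root-to-
leaf order reflects stepwise event accumulation.

## Signature scores and group statistics

The per-cell gene-set score ranks all N genes within a cell (average ranks
for ties) and maps the set's mean rank to (−1, 1]:
`(mean_rank − (N+1)/2) / ((N−1)/2)`. It is invariant under any strictly
monotone transform of a cell's expression vector, hence normalization-free,
and is an order-preserving single-cell stand-in for kernel-density
enrichment scores; all downstream uses compare score distributions between
groups, for which score order is what matters. Cell-cycle phase: G1 when
both S and G2M scores are ≤0, otherwise the larger positive score wins,
ties to S. Cell-cycle gene sets are user-supplied (GMT) — none ship as
canon.

The rank-sum engine computes the exact tie-aware permutation distribution of
the rank sum (dynamic program over doubled ranks) when both groups have ≤10
observations, and otherwise the normal approximation with tie and continuity
corrections; two-sided p is `P(|W − E[W]| ≥ |W_obs − E[W]|)`. DEG runs this
per gene on log2(CP10K+1) with log2FC as the difference of group means in
that space, testing genes expressed in ≥3 pooled cells, Bonferroni (or BH)
over tested genes. Cluster-vs-pooled-mean comparisons use the one-sample
signed-rank test with BH across clusters.

## Marker discovery

Per sample: genes with Bonferroni-adjusted p < 0.05 and log2FC > 0.25 in
tumor vs all non-malignant MNCs, and (LN only) vs normal T_FH cells, with
≥20 cells per side. Compartment candidates need recurrence in ≥2 samples
for every applicable background; final candidates are the LN ∩ PB
intersection, sorted by combined recurrence then symbol. The log2FC gate
and the final specificity rule — candidate expressed in <10% of pooled
non-malignant cells — replace a manual embedding-inspection step with a
reproducible criterion; both are parameters.

## Spatial and crosstalk permutation tests

Neighbor graphs per image: radius rule (default 15 µm, about one cell
diameter) or symmetrized k-NN. The ordered-pair statistic is the mean count
of type-B neighbors per type-A cell; the null shuffles all type labels
jointly within the image (graph and abundances preserved, the standard
neighborhood-analysis null); `p = (1 + #{null ≥ obs})/(n_perm + 1)` and the
avoidance mirror, 1000 permutations and α = 0.01 by default. A zero null SD
(e.g., a single type) is flagged degenerate, classification `none`. Both
orderings of each pair are reported, matrix-style. Ligand–receptor scores:
cluster-mean log2(CP10K+1) per side, complexes valued at their weakest
member, pair score the mean of the two sides, filtered unless each side is
expressed in ≥10% of its cluster's cells; the permutation null shuffles
cluster labels and the observed-configuration filter is not re-applied to
null draws (the null must stay well defined).

## Cohort summaries

Recurrence percentages are `100·count/total` rounded half-up to one decimal
— the reporting convention for count pairs like 11/14 → 78.6. Cluster
proportions are per-sample fractions of non-malignant cells, compared
between clinical groups by rank-sum with BH across clusters; groups with
fewer than two samples are skipped. Proportion tests are compositional:
an expansion of one cluster necessarily depresses the others' fractions.

## Problem sizes and determinism

The test and acceptance workloads use 1,500–2,000 cells, a 1,500-gene
miniature transcriptome, 100–300 permutations per spatial/crosstalk test,
and 100–200 simulated images or runs for calibration checks — sizes at which
every planted effect is comfortably detectable and the suites run in
minutes on one CPU. All randomness flows from explicit seeds; reruns are
bit-identical.

## Known limitations

- No transcriptome-wide co-expression, doublets, ambient RNA, or batch
  effects in the generator; recovery results bound best-case behavior.
- TRA-only single-chain tumor cells below the major threshold escape
  TRB-based clone linking (see above).
- The CNV caller assumes the reference set is copy-neutral; a contaminated
  reference biases all profiles.
- Exact rank-sum enumeration is only engaged for groups of ≤10; beyond that
  the asymptotic approximation is standard but approximate.
- The crosstalk module ships only a token built-in pair list; real analyses
  must supply a curated ligand–receptor table.
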