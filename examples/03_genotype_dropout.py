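"""Per-cell mutation genotyping under allelic dropout.

In scRNA-seq, a cell with no mutant reads is not wild type: transcript
capture fails often. Cells of a mutant-by-WES patient are MUT with >=1
alternate read and otherwise 'unknown'; the MUT fraction is predicted by
capture_prob x P(coverage > 0).
"""

import numpy as np

from tfhlkit import genotyping as gt
from tfhlkit import simulate as sim

capture, mean_cov = 0.9, 5.0
config = sim.SimConfig(
    populations=(sim.PopulationSpec("tumor", 2000, is_tumor=True),),
    mutation_specs=(sim.MutationSpec("RHOA_G17V", True, capture, mean_cov),),
    chromosomes={"chr1": 10},
    seed=2,
)
_, truth = sim.generate_expression(config)
pileup = sim.generate_pileups(config, truth)

kept = gt.filter_loci(pileup)  # coverage >= 100x and > 20 mutant cells
print(f"loci passing filters: {kept}")

calls = gt.call_genotypes(pileup, gt.Locus("RHOA_G17V", gt.MUTANT_BY_WES))
summary = gt.genotype_fraction_summary(calls).iloc[0]
expected = capture * (1 - np.exp(-mean_cov))
print(f"MUT fraction:        {summary['frac_mut']:.3f} (closed form {expected:.3f})")
print(f"covered, no alt:     {summary['frac_no_mutant_read']:.3f}")
print(f"no coverage:         {summary['frac_no_coverage']:.3f}")
# The three fractions partition the mutant patient's cells; the gap between
# MUT fraction and 1.0 is pure dropout, not wild-type cells.
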