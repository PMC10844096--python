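"""Generate a synthetic TFHL sample and inspect its ground truth.

Plants a dominant tumor TCR clone (40% of cells, 30% of them single-chain),
a chr5 x1.5 dosage gain in half the tumor cells, and a hotspot mutation with
capture dropout, then writes the full fixture set to ./example_dataset.
"""

from tfhlkit import simulate as sim

config = sim.SimConfig(
    populations=(
        sim.PopulationSpec("tumor_TFH", 400, is_tumor=True),
        sim.PopulationSpec("normal_T", 600),
    ),
    tumor_clone_specs=(sim.CloneSpec("clone1", fraction=1.0, single_chain_fraction=0.3),),
    cnv_events=(sim.CNVEvent("chr5", dosage=1.5, carrier_fraction=0.5),),
    mutation_specs=(sim.MutationSpec("RHOA_G17V", True, capture_prob=0.6, mean_coverage=5.0),),
    spatial_spec=sim.SpatialSpec(
        n_images=2, background_counts={"Tumor": 150, "CD8_TEFF": 150},
        attraction_pairs=(sim.AttractionPair("Tumor", "CD8_TDYS"),),
    ),
    seed=0,
)

out = sim.write_dataset(config, "example_dataset")
matrix, truth = sim.generate_expression(config)

print(f"dataset written to {out}/")
print(f"cells: {matrix.n_cells}, genes: {matrix.n_genes}")
print(f"tumor cells: {int(truth.cells['is_tumor'].sum())} "
      f"({truth.cells['is_tumor'].mean():.0%} of all cells)")
print(f"chr5-gain carriers: {int(truth.cnv_carriers['chr5|1.5'].sum())}")
print(f"true mutant cells: {int(truth.mutation_status['RHOA_G17V'].sum())}")
# Every downstream example recovers one of these planted structures from the
# data alone; the truth labels exist only to check the recovery.
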