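"""Tumor-specific marker discovery across samples and compartments.

Per sample, genes up-regulated in tumor cells vs all non-malignant MNCs (and
vs normal TFH cells in lymph nodes) are collected; genes recurrent in >= 2
samples per compartment are intersected across LN and PB, keeping only genes
expressed in < 10% of pooled non-malignant cells.
"""

from tfhlkit import markers as mk
from tfhlkit import simulate as sim

PAN = ("G0010", "G0011", "G0012")   # planted in every sample's tumor cells
samples = []
for i, (sid, comp, decoy) in enumerate([
    ("LN1", "LN", "G0020"), ("LN2", "LN", "G0020"),   # LN-only decoy
    ("PB1", "PB", "G0021"), ("PB2", "PB", "G0021"),   # PB-only decoy
]):
    pops = [sim.PopulationSpec("tumor", 120, is_tumor=True),
            sim.PopulationSpec("MNC", 200)]
    if comp == "LN":
        pops.append(sim.PopulationSpec("normal_TFH", 60))
    cfg = sim.SimConfig(populations=tuple(pops), marker_genes=PAN + (decoy,),
                        chromosomes={"chr1": 60}, seed=40 + i)
    matrix, truth = sim.generate_expression(cfg)
    cells = truth.cells.set_index("barcode")
    samples.append(mk.SampleInput(
        sid, comp, matrix,
        tumor_barcodes=cells.index[cells["population"] == "tumor"].tolist(),
        mnc_barcodes=cells.index[cells["population"] == "MNC"].tolist(),
        normal_tfh_barcodes=cells.index[cells["population"] == "normal_TFH"].tolist(),
    ))

candidates = mk.find_tumor_markers(samples)
print(candidates.to_string(index=False))
print(f"\nplanted pan-compartment markers: {sorted(PAN)}")
print("compartment-specific decoys are filtered by the LN-PB intersection")
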