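import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from tfhlkit import simulate as sim
from tfhlkit.io import CountMatrix


@pytest.fixture(scope="session")
def small_clone_config():
    """2,000 T cells: an 800-cell tumor clone (40%), 30% single-chain."""
    return sim.SimConfig(
        populations=(
            sim.PopulationSpec("tumor_TFH", 800, is_tumor=True),
            sim.PopulationSpec("normal_T", 1200),
        ),
        tumor_clone_specs=(sim.CloneSpec("clone1", fraction=1.0, single_chain_fraction=0.3),),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_clone_data(small_clone_config):
    matrix, truth = sim.generate_expression(small_clone_config)
    contigs = sim.generate_contigs(small_clone_config, truth)
    return matrix, truth, contigs


@pytest.fixture
def tiny_counts():
    """5 genes x 4 cells with hand-checkable counts."""
    counts = np.array([
        [5, 0, 1, 2],
        [0, 3, 1, 0],
        [2, 2, 2, 2],
        [0, 0, 4, 1],
        [1, 1, 0, 3],
    ])
    return CountMatrix(
        genes=[f"g{i}" for i in range(5)],
        barcodes=[f"c{i}" for i in range(4)],
        counts=sp.csr_matrix(counts),
    )


def make_truth(populations, loci=()):
    """Build a SyntheticTruth cell roster directly (no expression sampling).

    ``populations`` is a list of (name, n_cells, is_tumor, clone_id); each
    locus in ``loci`` marks all tumor cells as true mutants.
    """
    rows = []
    for name, n, is_tumor, clone in populations:
        for _ in range(n):
            rows.append((name, is_tumor, "LN", clone if is_tumor else ""))
    cells = pd.DataFrame(rows, columns=["population", "is_tumor", "tissue", "clone_id"])
    cells.insert(0, "barcode", [f"CELL{i:05d}-1" for i in range(len(cells))])
    empty = pd.DataFrame(index=cells["barcode"])
    muts = pd.DataFrame(
        {locus: cells["is_tumor"].to_numpy() for locus in loci}, index=cells["barcode"]
    ) if loci else empty.copy()
    return sim.SyntheticTruth(cells=cells, cnv_carriers=empty.copy(), mutation_status=muts)
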