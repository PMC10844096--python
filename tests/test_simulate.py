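import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from tfhlkit import simulate as sim
from conftest import make_truth


def small_config(**kwargs):
    defaults = dict(
        populations=(
            sim.PopulationSpec("tumor", 100, is_tumor=True),
            sim.PopulationSpec("T", 150),
        ),
        chromosomes={"chr1": 30, "chr5": 30},
        seed=5,
    )
    defaults.update(kwargs)
    return sim.SimConfig(**defaults)


class TestGenerateExpression:
    def test_same_seed_identical_matrices(self):
        a, _ = sim.generate_expression(small_config())
        b, _ = sim.generate_expression(small_config())
        assert (a.counts != b.counts).nnz == 0
        assert a.barcodes == b.barcodes

    def test_cell_conservation_and_unique_truth(self):
        cfg = small_config()
        matrix, truth = sim.generate_expression(cfg)
        assert matrix.n_cells == sum(p.n_cells for p in cfg.populations)
        assert truth.cells["barcode"].is_unique
        assert set(truth.cells["barcode"]) == set(matrix.barcodes)

    def test_no_event_no_dosage_difference(self):
        cfg = small_config(cnv_events=(sim.CNVEvent("chr5", 1.0, 0.5),))
        matrix, truth = sim.generate_expression(cfg)
        carriers = truth.cnv_carriers.iloc[:, 0]
        chr5 = [i for i, g in enumerate(matrix.genes) if i >= 30]  # chr5 genes
        dense = matrix.dense()
        mean_c = dense[np.ix_(chr5, np.flatnonzero(carriers.to_numpy()))].mean()
        mean_n = dense[np.ix_(chr5, np.flatnonzero(~carriers.to_numpy()))].mean()
        assert abs(mean_c - mean_n) < 0.15  # sampling error only

    def test_dosage_ratio_in_poisson_limit(self):
        # 2000 carrier cells at dosage 1.5, dispersion -> infinity
        cfg = sim.SimConfig(
            populations=(sim.PopulationSpec("tumor", 4000, is_tumor=True),),
            cnv_events=(sim.CNVEvent("chr5", 1.5, 0.5),),
            chromosomes={"chr1": 20, "chr5": 20},
            nb_dispersion=float("inf"),
            seed=7,
        )
        matrix, truth = sim.generate_expression(cfg)
        carriers = truth.cnv_carriers.iloc[:, 0].to_numpy()
        dense = matrix.dense()
        chr5 = slice(20, 40)
        mu = cfg.nb_mean
        m_c = dense[chr5, carriers].mean()
        m_n = dense[chr5, ~carriers].mean()
        n_obs = 20 * carriers.sum()
        se_ratio = np.sqrt(1.5 * mu / n_obs + (1.5**2) * mu / n_obs) / mu
        assert abs(m_c / m_n - 1.5) < 2 * se_ratio + 0.02

    def test_marker_genes_restricted_to_tumor(self):
        cfg = small_config(marker_genes=("G0003",))
        matrix, truth = sim.generate_expression(cfg)
        dense = matrix.dense()
        gi = matrix.genes.index("G0003")
        tumor = truth.cells["is_tumor"].to_numpy()
        assert dense[gi, tumor].mean() > 10 * max(dense[gi, ~tumor].mean(), 0.01)

    def test_unknown_program_gene_named(self):
        cfg = small_config(populations=(
            sim.PopulationSpec("tumor", 10, program_genes=("NOPE",), is_tumor=True),
        ))
        with pytest.raises(ValueError, match="NOPE"):
            sim.generate_expression(cfg)

    def test_empty_population_list_rejected(self):
        with pytest.raises(ValueError, match="populations"):
            sim.SimConfig(populations=())


class TestGenerateContigs:
    def test_zero_single_chain_gives_all_paired(self):
        cfg = small_config(tumor_clone_specs=(sim.CloneSpec("c1", 1.0, 0.0),))
        truth = make_truth([("tumor", 100, True, "c1"), ("T", 50, False, "")])
        contigs = sim.generate_contigs(cfg, truth)
        tumor_bc = set(truth.cells.loc[truth.cells["is_tumor"], "barcode"])
        per_cell = contigs[contigs["barcode"].isin(tumor_bc)].groupby("barcode")["chain"]
        assert all(sorted(chains) == ["TRA", "TRB"] for _, chains in per_cell)

    def test_shared_trb_distinct_tra_two_clonotype_keys(self):
        trb = "TGT" * 12
        cfg = small_config(tumor_clone_specs=(
            sim.CloneSpec("c1", 0.5, 0.0, trb_nt=trb),
            sim.CloneSpec("c2", 0.5, 0.0, trb_nt=trb),
        ))
        truth = make_truth([("tumor", 40, True, "c1"), ("tumor", 40, True, "c2")])
        contigs = sim.generate_contigs(cfg, truth)
        tras = contigs[contigs["chain"] == "TRA"]["cdr3_nt"].unique()
        trbs = contigs[contigs["chain"] == "TRB"]["cdr3_nt"].unique()
        assert len(trbs) == 1 and trbs[0] == trb
        assert len(tras) == 2

    def test_single_chain_count_binomial_across_seeds(self):
        # mean single-chain tumor cells over 100 seeds = 300 +/- 3 SE at n=1000, p=0.3
        truth = make_truth([("tumor", 1000, True, "c1")])
        counts = []
        for seed in range(100):
            cfg = small_config(tumor_clone_specs=(sim.CloneSpec("c1", 1.0, 0.3),), seed=seed)
            contigs = sim.generate_contigs(cfg, truth)
            n_chains = contigs.groupby("barcode").size()
            counts.append(int((n_chains == 1).sum()))
        mean = np.mean(counts)
        se = np.sqrt(1000 * 0.3 * 0.7 / 100)
        assert abs(mean - 300) < 3 * se

    def test_nontumor_cells_unique_except_expanded(self):
        cfg = small_config(expanded_clones=(sim.ExpandedCloneSpec("cd8x", 20),))
        truth = make_truth([("T", 150, False, "")])
        contigs = sim.generate_contigs(cfg, truth)
        keys = contigs.groupby("barcode").apply(
            lambda g: tuple(sorted(g["cdr3_nt"])), include_groups=False)
        sizes = keys.value_counts()
        assert sizes.max() == 20
        assert (sizes == 1).sum() == 130


class TestGeneratePileups:
    def test_full_capture_every_covered_mutant_has_alt(self):
        cfg = small_config(mutation_specs=(sim.MutationSpec("L1", True, 1.0, 50.0),))
        truth = make_truth([("tumor", 200, True, "c1"), ("T", 100, False, "")], loci=["L1"])
        pile = sim.generate_pileups(cfg, truth)
        is_mut = truth.mutation_status["L1"].to_numpy()
        covered_mut = pile[is_mut & (pile["total"] > 0)]
        assert (covered_mut["alt_reads"] >= 1).all()

    def test_zero_capture_no_alt_anywhere(self):
        cfg = small_config(mutation_specs=(sim.MutationSpec("L1", True, 0.0, 5.0),))
        truth = make_truth([("tumor", 300, True, "c1")], loci=["L1"])
        pile = sim.generate_pileups(cfg, truth)
        assert (pile["alt_reads"] == 0).all()

    def test_nonmutant_cells_never_alt(self):
        cfg = small_config(mutation_specs=(sim.MutationSpec("L1", True, 0.9, 5.0),))
        truth = make_truth([("tumor", 100, True, "c1"), ("T", 400, False, "")], loci=["L1"])
        pile = sim.generate_pileups(cfg, truth)
        nonmut = ~truth.mutation_status["L1"].to_numpy()
        assert (pile.loc[nonmut, "alt_reads"] == 0).all()

    def test_alt_fraction_matches_bernoulli_poisson(self):
        capture, cov = 0.6, 3.0
        cfg = small_config(mutation_specs=(sim.MutationSpec("L1", True, capture, cov),))
        truth = make_truth([("tumor", 500, True, "c1")], loci=["L1"])
        pile = sim.generate_pileups(cfg, truth)
        frac = (pile["alt_reads"] >= 1).mean()
        expected = capture * (1 - np.exp(-cov))
        se = np.sqrt(expected * (1 - expected) / 500)
        assert abs(frac - expected) < 3 * se


class TestGenerateSpatial:
    def _spatial_config(self, **spatial_kwargs):
        defaults = dict(n_images=1, field_size=400.0,
                        background_counts={"A": 150, "B": 150})
        defaults.update(spatial_kwargs)
        return small_config(spatial_spec=sim.SpatialSpec(**defaults))

    def test_attraction_shortens_nearest_neighbor_distance(self):
        # CSR Monte-Carlo oracle for the mean nearest A-B distance
        rng = np.random.default_rng(0)
        cfg = self._spatial_config(
            background_counts={"C": 100},
            attraction_pairs=(sim.AttractionPair("A", "B", cluster_radius=20.0),))
        cells, _ = sim.generate_spatial(cfg)
        a = cells[cells["cell_type"] == "A"][["x_um", "y_um"]].to_numpy()
        b = cells[cells["cell_type"] == "B"][["x_um", "y_um"]].to_numpy()
        observed = cKDTree(b).query(a)[0].mean()
        null = []
        for _ in range(30):
            ra = rng.random((len(a), 2)) * 400
            rb = rng.random((len(b), 2)) * 400
            null.append(cKDTree(rb).query(ra)[0].mean())
        assert observed < np.percentile(null, 1)

    def test_disjoint_halves_no_cross_neighbors_at_small_radius(self):
        cfg = self._spatial_config(background_counts={},
                                   avoidance_pairs=(sim.AvoidancePair("A", "B"),))
        cells, _ = sim.generate_spatial(cfg)
        a = cells[cells["cell_type"] == "A"][["x_um", "y_um"]].to_numpy()
        b = cells[cells["cell_type"] == "B"][["x_um", "y_um"]].to_numpy()
        pairs = cKDTree(a).query_ball_tree(cKDTree(b), r=400 / 4 - 1e-9)
        assert sum(len(p) for p in pairs) == 0

    def test_contradictory_pair_rejected(self):
        with pytest.raises(ValueError, match="attracted and avoided"):
            self._spatial_config(
                attraction_pairs=(sim.AttractionPair("A", "B"),),
                avoidance_pairs=(sim.AvoidancePair("B", "A"),))

    def test_determinism(self):
        cfg = self._spatial_config()
        a, _ = sim.generate_spatial(cfg)
        b, _ = sim.generate_spatial(cfg)
        pd.testing.assert_frame_equal(a, b)


def test_write_dataset_round_trips(tmp_path):
    from tfhlkit import io as tio
    cfg = small_config(
        tumor_clone_specs=(sim.CloneSpec("c1", 1.0, 0.2),),
        mutation_specs=(sim.MutationSpec("L1", True, 0.6, 5.0),),
        spatial_spec=sim.SpatialSpec(n_images=1, background_counts={"A": 50, "B": 50}),
    )
    out = sim.write_dataset(cfg, tmp_path / "ds")
    matrix = tio.read_count_matrix(out)
    assert matrix.n_cells == 250
    contigs = tio.read_contigs(out / "filtered_contig_annotations.csv")
    assert set(contigs["barcode"]).issubset(set(matrix.barcodes))
    pile = tio.read_pileup(out / "pileup.tsv")
    assert len(pile) == 250
    spatial = tio.read_spatial(out / "spatial_cells.csv")
    assert set(spatial["cell_type"]) == {"A", "B"}
    assert (out / "truth.json").exists()
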