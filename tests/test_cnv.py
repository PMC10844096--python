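import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from tfhlkit import cnv as tc
from tfhlkit import simulate as sim
from tfhlkit.io import CountMatrix


def positions_for(genes, chrom="chr1"):
    return pd.DataFrame({
        "gene": genes, "chrom": chrom,
        "start": np.arange(1, len(genes) + 1) * 1000,
        "end": np.arange(1, len(genes) + 1) * 1000 + 100,
    })


class TestRelativeExpression:
    def test_query_equal_to_reference_mean_is_zero(self):
        # identical cells: every cell IS the reference mean
        dense = np.tile([[4], [2], [8], [1], [3]], (1, 6))
        m = CountMatrix([f"g{i}" for i in range(5)], [f"c{i}" for i in range(6)],
                        sp.csr_matrix(dense))
        rel, genes, chroms = tc.compute_relative_expression(
            m, positions_for(m.genes), ["c0", "c1", "c2"])
        np.testing.assert_allclose(rel, 0.0, atol=1e-12)

    def test_noiseless_dosage_shift_is_log2_ratio(self):
        # noiseless 1.5x gain on a chromosome holding a small share of the
        # transcriptome (as in a real genome) shifts its genes by ~log2(1.5);
        # the tiny compositional residual from library normalization stays
        # inside the tolerance
        n_genes, n_chr5 = 400, 8
        genes = [f"g{i}" for i in range(n_genes)]
        pos = pd.concat([positions_for(genes[:-n_chr5], "chr1"),
                         positions_for(genes[-n_chr5:], "chr5")], ignore_index=True)
        base = np.full((n_genes, 4), 64.0)
        gained = base.copy()
        gained[-n_chr5:, :] *= 1.5
        dense = np.hstack([base, gained])
        m = CountMatrix(genes, [f"c{i}" for i in range(8)], sp.csr_matrix(dense.round()))
        rel, out_genes, chroms = tc.compute_relative_expression(m, pos, [f"c{i}" for i in range(4)])
        chr5_cols = np.array([c == "chr5" for c in chroms])
        carrier_rows = rel[4:]
        assert carrier_rows[:, chr5_cols].mean() == pytest.approx(np.log2(1.5), abs=0.05)
        assert abs(carrier_rows[:, ~chr5_cols].mean()) < 0.05

    def test_clipping(self):
        genes = [f"g{i}" for i in range(10)]
        dense = np.ones((10, 4))
        dense[0, 3] = 500.0  # extreme cell
        m = CountMatrix(genes, [f"c{i}" for i in range(4)], sp.csr_matrix(dense))
        rel, _, _ = tc.compute_relative_expression(m, positions_for(genes), ["c0", "c1"])
        assert rel.max() <= 1.0 and rel.min() >= -1.0

    def test_empty_reference_rejected(self):
        m = CountMatrix(["g0"] * 0 + ["g0"], ["c0"], sp.csr_matrix(np.ones((1, 1))))
        with pytest.raises(ValueError, match="reference"):
            tc.compute_relative_expression(m, positions_for(["g0"]), [])

    def test_genes_without_positions_dropped(self):
        genes = [f"g{i}" for i in range(12)]
        m = CountMatrix(genes, ["c0", "c1"], sp.csr_matrix(np.ones((12, 2))))
        pos = positions_for(genes[:8])
        rel, kept, _ = tc.compute_relative_expression(m, pos, ["c0"])
        assert kept == genes[:8]


class TestSmoothing:
    def test_constant_input_gives_zero(self):
        rel = np.full((3, 30), 0.7)
        prof = tc.smooth_by_position(rel, [f"g{i}" for i in range(30)],
                                     np.array(["chr1"] * 30), ["a", "b", "c"], window=5)
        np.testing.assert_allclose(prof.values, 0.0, atol=1e-12)

    def test_window_one_median_zero_is_identity(self):
        rng = np.random.default_rng(0)
        rel = rng.normal(0, 1, size=(4, 21))
        rel -= np.median(rel, axis=1, keepdims=True)
        prof = tc.smooth_by_position(rel, [f"g{i}" for i in range(21)],
                                     np.array(["chr1"] * 21), list("abcd"), window=1)
        np.testing.assert_allclose(prof.values, rel, atol=1e-12)

    def test_step_input_matches_direct_convolution_oracle(self):
        step = np.concatenate([np.zeros(20), np.ones(20)])[None, :]
        window = 7
        prof = tc.smooth_by_position(step, [f"g{i}" for i in range(40)],
                                     np.array(["chr1"] * 40), ["cell"], window=window)
        # brute-force centered moving average with shrinking edges
        expected = np.array([
            step[0, max(0, i - window // 2): i + window // 2 + 1].mean()
            for i in range(40)
        ])
        expected -= np.median(expected)
        np.testing.assert_allclose(prof.values[0], expected, atol=1e-12)

    def test_chromosomes_smoothed_independently(self):
        rel = np.concatenate([np.zeros(15), np.ones(15)])[None, :]
        chroms = np.array(["chr1"] * 15 + ["chr2"] * 15)
        prof = tc.smooth_by_position(rel, [f"g{i}" for i in range(30)], chroms, ["c"], window=5)
        vals = prof.values[0] + np.median(np.concatenate([np.zeros(15), np.ones(15)]))
        # no bleed across the chromosome boundary
        np.testing.assert_allclose(vals[:15], 0.0, atol=1e-9)
        np.testing.assert_allclose(vals[15:], 1.0, atol=1e-9)

    def test_oversized_window_shrunk_with_warning(self):
        rel = np.zeros((1, 6))
        with pytest.warns(UserWarning, match="too wide"):
            tc.smooth_by_position(rel, [f"g{i}" for i in range(6)],
                                  np.array(["chr1"] * 6), ["c"], window=101)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            tc.smooth_by_position(np.zeros((1, 4)), list("abcd"),
                                  np.array(["chr1"] * 4), ["c"], window=4)


def profile_of(values, chroms):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return tc.CNVProfile(values=values, barcodes=[f"c{i}" for i in range(values.shape[0])],
                         genes=[f"g{i}" for i in range(values.shape[1])],
                         chroms=np.asarray(chroms), window=1)


class TestChromosomeCalls:
    def test_all_zero_neutral(self):
        prof = profile_of(np.zeros(10), ["chr1"] * 10)
        out = tc.call_chromosome_cnv(prof)
        assert out["state"].tolist() == ["neutral"]

    def test_sixty_percent_positive_windows_is_gain(self):
        vals = np.array([0.3] * 6 + [0.0] * 4)
        out = tc.call_chromosome_cnv(profile_of(vals, ["chr1"] * 10))
        assert out["state"].tolist() == ["gain"]
        assert out["frac_gain"].iloc[0] == pytest.approx(0.6)

    def test_sixty_percent_negative_windows_is_loss(self):
        vals = np.array([-0.3] * 6 + [0.0] * 4)
        out = tc.call_chromosome_cnv(profile_of(vals, ["chr1"] * 10))
        assert out["state"].tolist() == ["loss"]

    def test_threshold_order_enforced(self):
        with pytest.raises(ValueError, match="exceed"):
            tc.call_chromosome_cnv(profile_of(np.zeros(4), ["chr1"] * 4),
                                   gain_threshold=-0.2, loss_threshold=0.2)


class TestCnvScore:
    def test_zero_profile_zero_score(self):
        assert tc.cnv_score(profile_of(np.zeros(8), ["chr1"] * 8)).iloc[0] == 0.0

    def test_constant_02_gives_004(self):
        assert tc.cnv_score(profile_of(np.full(8, 0.2), ["chr1"] * 8)).iloc[0] == \
            pytest.approx(0.04)

    def test_gain_strictly_increases_score(self):
        flat = np.zeros(20)
        gained = flat.copy()
        gained[10:] = 0.5
        scores = tc.cnv_score(profile_of(np.vstack([flat, gained]), ["chr1"] * 20))
        assert scores.iloc[1] > scores.iloc[0]

    def test_invariant_to_gene_permutation(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 0.3, size=(3, 15))
        perm = rng.permutation(15)
        s1 = tc.cnv_score(profile_of(vals, ["chr1"] * 15))
        s2 = tc.cnv_score(profile_of(vals[:, perm], ["chr1"] * 15))
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy())


class TestSubclones:
    def test_two_planted_groups_recovered(self):
        rng = np.random.default_rng(2)
        neutral = rng.normal(0, 0.05, size=(200, 60))
        gained = rng.normal(0, 0.05, size=(200, 60))
        gained[:, 30:] += 0.58  # one gained chromosome half
        prof = profile_of(np.vstack([neutral, gained]), ["chr1"] * 60)
        labels = tc.cluster_subclones(prof, k=2)
        truth = np.array([0] * 200 + [1] * 200)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(truth, labels.to_numpy()) >= 0.9

    def test_k_one_single_label(self):
        prof = profile_of(np.random.default_rng(3).normal(size=(10, 5)), ["chr1"] * 5)
        assert tc.cluster_subclones(prof, k=1).nunique() == 1

    def test_k_exceeding_cells_rejected(self):
        prof = profile_of(np.zeros((3, 4)), ["chr1"] * 4)
        with pytest.raises(ValueError, match="exceeds"):
            tc.cluster_subclones(prof, k=5)


def nj_oracle(dist, ids):
    """Independent textbook neighbor joining; returns tip-pair path lengths.

    Maintains an explicit edge-weighted graph; at each step joins the pair
    minimizing the Q criterion and computes classic NJ branch lengths.
    """
    import networkx as nx
    g = nx.Graph()
    active = {name: name for name in ids}
    d = {frozenset((a, b)): float(dist[i, j])
         for i, a in enumerate(ids) for j, b in enumerate(ids) if i < j}
    nodes = list(ids)
    new_id = 0
    while len(nodes) > 2:
        r = len(nodes)
        q_best, pair = None, None
        for i in range(r):
            for j in range(i + 1, r):
                a, b = nodes[i], nodes[j]
                q = (r - 2) * d[frozenset((a, b))] \
                    - sum(d[frozenset((a, k))] for k in nodes if k != a) \
                    - sum(d[frozenset((b, k))] for k in nodes if k != b)
                if q_best is None or q < q_best:
                    q_best, pair = q, (a, b)
        a, b = pair
        u = f"_u{new_id}"; new_id += 1
        dab = d[frozenset((a, b))]
        ra = sum(d[frozenset((a, k))] for k in nodes if k != a)
        rb = sum(d[frozenset((b, k))] for k in nodes if k != b)
        la = 0.5 * dab + (ra - rb) / (2 * (r - 2))
        lb = dab - la
        g.add_edge(a, u, weight=la)
        g.add_edge(b, u, weight=lb)
        nodes = [n for n in nodes if n not in (a, b)]
        for k in nodes:
            d[frozenset((u, k))] = 0.5 * (d[frozenset((a, k))] + d[frozenset((b, k))] - dab)
        nodes.append(u)
    g.add_edge(nodes[0], nodes[1], weight=d[frozenset((nodes[0], nodes[1]))])
    out = {}
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i < j:
                out[(a, b)] = nx.shortest_path_length(g, a, b, weight="weight")
    return out


class TestCloneTree:
    def test_single_subclone_root_leaf_distance(self):
        means = pd.DataFrame([[0.3, 0.4]], index=["s1"])
        tree = tc.build_clone_tree(means)
        tip = tree.find("s1")
        assert tip.length == pytest.approx(0.5)

    def test_nested_gain_attaches_within_gain_branch(self):
        # subclones: neutral-like, chr5 gain, chr5+chr21 gain
        n = 30
        neutral = np.zeros(3 * n)
        chr5 = neutral.copy(); chr5[n:2 * n] = 0.58
        chr5_21 = chr5.copy(); chr5_21[2 * n:] = 0.58
        means = pd.DataFrame([neutral, chr5, chr5_21], index=["bulk", "g5", "g5_21"])
        tree = tc.build_clone_tree(means)
        # in the rooted tree the two gain subclones are siblings apart from bulk
        g5 = tree.find("g5")
        lca = tree.lowest_common_ancestor(["g5", "g5_21"])
        assert "bulk" not in [t.name for t in lca.tips()]

    def test_tree_distances_match_independent_nj_oracle(self):
        rng = np.random.default_rng(4)
        profiles = pd.DataFrame(rng.normal(0, 0.4, size=(4, 12)),
                                index=["a", "b", "c", "d"])
        tree = tc.build_clone_tree(profiles)
        full = np.vstack([profiles.to_numpy(), np.zeros(12)])
        ids = ["a", "b", "c", "d", "neutral"]
        from scipy.spatial.distance import pdist, squareform
        d = squareform(pdist(full))
        expected = nj_oracle(d, ids)
        for (a, b), dist_ab in expected.items():
            td = tree.find(a).distance(tree.find(b))
            assert td == pytest.approx(dist_ab, abs=1e-8)

    def test_root_name_collision_rejected(self):
        means = pd.DataFrame([[0.1]], index=["neutral"])
        with pytest.raises(ValueError, match="collides"):
            tc.build_clone_tree(means)


class TestEndToEndRecovery:
    def test_planted_gain_sensitivity_and_specificity(self):
        cfg = sim.SimConfig(
            populations=(sim.PopulationSpec("tumor", 300, is_tumor=True),
                         sim.PopulationSpec("T", 450)),
            cnv_events=(sim.CNVEvent("chr5", 1.5, 0.5),),
            chromosomes={c: 150 for c in ["chr1", "chr2", "chr5", "chr7"]},
            seed=13,
        )
        matrix, truth = sim.generate_expression(cfg)
        ref = truth.cells.loc[~truth.cells["is_tumor"], "barcode"].tolist()
        rel, genes, chroms = tc.compute_relative_expression(matrix, cfg.gene_table(), ref)
        prof = tc.smooth_by_position(rel, genes, chroms, matrix.barcodes, window=101)
        calls = tc.call_chromosome_cnv(prof)
        carriers = truth.cnv_carriers.iloc[:, 0]
        chr5 = calls[calls["chrom"] == "chr5"].set_index("barcode")["state"]
        sensitivity = (chr5[carriers[carriers].index] == "gain").mean()
        false_gain = (calls[calls["chrom"] != "chr5"]["state"] == "gain").mean()
        assert sensitivity >= 0.9
        assert false_gain <= 0.05
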