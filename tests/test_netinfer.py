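import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from omnileaf.netinfer import (
    AggregatedNetwork,
    EdgeScoreSet,
    aggregate_irp,
    backbone,
    centralities,
    filter_and_adjust,
    infer,
    partition,
    scale_free_fit,
    summary_stats,
)


def _expr(X, prefix="g"):
    return pd.DataFrame(
        X, index=[f"{prefix}{i}" for i in range(X.shape[0])],
        columns=[f"s{j}" for j in range(X.shape[1])],
    )


def _net_from_edges(edge_list):
    """AggregatedNetwork from explicit (a, b, weight) triples."""

    genes = sorted({a for a, _, _ in edge_list} | {b for _, b, _ in edge_list})
    df = pd.DataFrame(edge_list, columns=["gene_a", "gene_b", "irp_score"])
    df["rank_product"] = 1.0 / df["irp_score"]
    return AggregatedNetwork(genes=genes, edges=df)


class TestFilterAndAdjust:
    def test_all_zero_gene_dropped(self):
        rng = np.random.default_rng(0)
        counts = _expr(rng.integers(5, 100, size=(20, 12)).astype(float))
        counts.iloc[3] = 0.0
        out = filter_and_adjust(counts, var_min=0.0)
        assert "g3" not in out.index

    def test_variance_boundary(self):
        # engineer log2-scale variances just below/above the threshold
        n = 10
        x = np.zeros((3, n))
        base = np.r_[np.full(n // 2, -1.0), np.full(n // 2, 1.0)]
        sd_lo, sd_hi = np.sqrt(0.049), np.sqrt(0.051)
        x[0] = 5.0 + base * sd_lo  # variance 0.049 (population = ddof 0... use exact)
        x[1] = 5.0 + base * sd_hi
        x[2] = 5.0 + base  # clearly above
        # adjust for ddof=1 variance: scale so that var(ddof=1) hits target
        for i, v in enumerate((0.049, 0.051, 1.0)):
            c = x[i] - x[i].mean()
            x[i] = 5.0 + c * np.sqrt(v / np.var(c, ddof=1))
        counts = _expr(np.exp2(x) - 1.0)
        sf = pd.Series(1.0, index=counts.columns)
        out = filter_and_adjust(counts, min_nonzero=1, var_min=0.05,
                                size_factors=sf)
        assert "g0" not in out.index
        assert "g1" in out.index

    def test_pc_removal_orthogonality(self):
        rng = np.random.default_rng(1)
        counts = _expr(rng.integers(10, 1000, size=(40, 15)).astype(float))
        full = filter_and_adjust(counts, var_min=0.0)
        k = 3
        adj = filter_and_adjust(counts, var_min=0.0, n_pcs=k)
        Xc = full.to_numpy() - full.to_numpy().mean(axis=1, keepdims=True)
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        for j in range(k):
            corr = adj.to_numpy() @ Vt[j]
            assert np.max(np.abs(corr)) < 1e-8

    def test_too_many_pcs_errors(self):
        rng = np.random.default_rng(2)
        counts = _expr(rng.integers(5, 50, size=(10, 8)).astype(float))
        with pytest.raises(ValueError):
            filter_and_adjust(counts, n_pcs=8)


class TestInfer:
    def test_identical_rows_pearson_one(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((5, 30))
        X[1] = X[0]
        s = infer(_expr(X), "pearson")
        # edge (0, 1) is the first condensed entry
        assert s.scores[0] == pytest.approx(1.0)

    def test_independent_rows_low_scores(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((30, 200))
        s = infer(_expr(X), "pearson")
        assert np.mean(s.scores) < 0.1
        c = infer(_expr(X), "clr")
        assert np.median(c.scores) < 1.5

    def test_pcor_chain_ranks_indirect_edge_lowest(self):
        rng = np.random.default_rng(5)
        n = 400
        x = rng.standard_normal(n)
        y = x + 0.5 * rng.standard_normal(n)
        z = y + 0.5 * rng.standard_normal(n)
        s = infer(_expr(np.vstack([x, y, z])), "pcor")
        # condensed order: (x,y), (x,z), (y,z)
        xy, xz, yz = s.scores
        assert xz < xy and xz < yz

    def test_constant_gene_zero_scores(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((4, 20))
        X[2] = 1.0
        for method in ("pearson", "spearman"):
            s = infer(_expr(X), method)
            iu = np.triu_indices(4, k=1)
            for k, (i, j) in enumerate(zip(*iu)):
                if 2 in (i, j):
                    assert s.scores[k] == 0.0

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            infer(_expr(np.ones((3, 5))), "pearson")

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            infer(_expr(np.ones((3, 20))), "genie3")


class TestAggregateIrp:
    def test_single_method_identity_order(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((10, 40))
        s = infer(_expr(X), "pearson")
        net = aggregate_irp([s])
        order_scores = np.argsort(-s.scores, kind="stable")
        iu = np.triu_indices(10, k=1)
        top = (iu[0][order_scores[0]], iu[1][order_scores[0]])
        assert net.edges.iloc[0]["gene_a"] == f"g{top[0]}"
        assert net.edges.iloc[0]["gene_b"] == f"g{top[1]}"

    def test_unanimous_best_edge_tops(self):
        genes = [f"g{i}" for i in range(4)]
        base = np.array([9.0, 1.0, 2.0, 3.0, 4.0, 5.0])  # edge 0 best
        sets = [
            EdgeScoreSet(m, genes, base + rng_shift)
            for m, rng_shift in (("a", 0.0), ("b", 0.1), ("c", 0.2))
        ]
        net = aggregate_irp(sets)
        assert net.edges.iloc[0]["rank_product"] == pytest.approx(1.0)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(10)]
        n_edges = 45
        sets = [
            EdgeScoreSet(f"m{k}", genes, rng.random(n_edges)) for k in range(3)
        ]
        net = aggregate_irp(sets)
        rp = np.ones(n_edges)
        for s in sets:
            order = np.argsort(-s.scores)
            ranks = np.empty(n_edges)
            ranks[order] = np.arange(1, n_edges + 1)
            rp *= ranks
        rp = rp ** (1.0 / 3.0)
        expected = np.sort(rp)
        assert np.allclose(
            net.edges["rank_product"].to_numpy(), expected, atol=1e-12
        )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(8)]
        s1 = EdgeScoreSet("a", genes, rng.random(28))
        s2 = EdgeScoreSet("b", genes, rng.random(28))
        net1 = aggregate_irp([s1, s2])
        s1t = EdgeScoreSet("a", genes, np.exp(5 * s1.scores))  # monotone
        net2 = aggregate_irp([s1t, s2])
        assert np.allclose(
            net1.edges["rank_product"].to_numpy(),
            net2.edges["rank_product"].to_numpy(),
        )

    def test_mismatched_universe_errors(self):
        s1 = EdgeScoreSet("a", ["g0", "g1", "g2"], np.ones(3))
        s2 = EdgeScoreSet("b", ["g0", "g1", "g3"], np.ones(3))
        with pytest.raises(ValueError):
            aggregate_irp([s1, s2])


class TestBackbone:
    def test_minus_inf_sigma_keeps_all(self):
        net = _net_from_edges(
            [("a", "b", 3.0), ("b", "c", 1.0), ("c", "d", 1.0)]
        )
        out = backbone(net, sigma=-np.inf)
        assert len(out.backbone_edges) == 3

    def test_nested_in_sigma(self):
        rng = np.random.default_rng(10)
        edges = []
        nodes = [f"n{i}" for i in range(12)]
        for i in range(12):
            for j in range(i + 1, 12):
                edges.append((nodes[i], nodes[j], float(rng.random() ** 3)))
        prev = None
        for sigma in (-1.0, 0.5, 1.5, 2.32, 4.0):
            net = _net_from_edges(edges)
            kept = set(
                map(tuple, backbone(net, sigma=sigma)
                    .backbone_edges[["gene_a", "gene_b"]].to_numpy())
            )
            if prev is not None:
                assert kept <= prev
            prev = kept

    def test_hand_computed_z_four_nodes(self):
        edges = [("a", "b", 8.0), ("b", "c", 1.0), ("c", "d", 1.0),
                 ("a", "d", 2.0)]
        net = backbone(_net_from_edges(edges), sigma=2.0, unit="raw")
        w = np.array([8.0, 1.0, 1.0, 2.0])
        T = w.sum()
        s = {"a": 10.0, "b": 9.0, "c": 2.0, "d": 3.0}
        for (ga, gb, wv), z in zip(edges, net.edges["backbone_z"]):
            p = s[ga] * s[gb] / T**2
            z_hand = (wv - T * p) / np.sqrt(T * p * (1 - p))
            assert z == pytest.approx(z_hand, rel=1e-12)

    def test_zero_total_weight(self):
        net = _net_from_edges([("a", "b", 1.0)])
        net.edges["irp_score"] = 0.0
        out = backbone(net)
        assert len(out.backbone_edges) == 0

    def test_negative_weight_rejected(self):
        net = _net_from_edges([("a", "b", 1.0)])
        net.edges["irp_score"] = -1.0
        with pytest.raises(ValueError):
            backbone(net)


class TestPartitionCentralities:
    @staticmethod
    def _two_cliques():
        edges = []
        for grp, nodes in (("x", ["x0", "x1", "x2", "x3"]),
                           ("y", ["y0", "y1", "y2"])):
            for i in range(len(nodes)):
                for j in range(i + 1, len(nodes)):
                    edges.append((nodes[i], nodes[j], 1.0))
        net = _net_from_edges(edges)
        net.backbone_edges = net.edges
        return net

    def test_two_cliques_two_clusters(self):
        net = self._two_cliques()
        labels = partition(net)
        x_labels = {labels[f"x{i}"] for i in range(4)}
        y_labels = {labels[f"y{i}"] for i in range(3)}
        assert len(x_labels) == 1 and len(y_labels) == 1
        assert x_labels != y_labels
        # larger component gets component index 1
        assert next(iter(x_labels)).startswith("1:")
        assert next(iter(y_labels)).startswith("2:")

    def test_star_graph_hub(self):
        edges = [("hub", f"leaf{i}", 1.0) for i in range(5)]
        net = _net_from_edges(edges)
        net.backbone_edges = net.edges
        cent = centralities(net)
        for metric in ("degree", "betweenness", "pagerank"):
            assert cent[metric].idxmax() == "hub"

    def test_cycle_symmetry(self):
        n = 6
        edges = [(f"c{i}", f"c{(i + 1) % n}", 1.0) for i in range(n)]
        net = _net_from_edges(edges)
        net.backbone_edges = net.edges
        cent = centralities(net)
        for metric in ("degree", "pagerank", "betweenness", "eigenvector"):
            vals = cent[metric].to_numpy()
            assert np.allclose(vals, vals[0], atol=1e-6)

    def test_pagerank_power_iteration_oracle(self):
        rng = np.random.default_rng(11)
        nodes = [f"n{i}" for i in range(6)]
        edges = []
        for i in range(6):
            for j in range(i + 1, 6):
                if rng.random() < 0.7:
                    edges.append((nodes[i], nodes[j], float(rng.random() + 0.1)))
        net = _net_from_edges(edges)
        net.backbone_edges = net.edges
        cent = centralities(net)
        G = net.graph()
        order = list(G.nodes)
        A = nx.to_numpy_array(G, nodelist=order, weight="weight")
        P = A / A.sum(axis=1, keepdims=True)
        v = np.ones(len(order)) / len(order)
        for _ in range(10000):
            v_new = 0.15 / len(order) + 0.85 * P.T @ v
            if np.max(np.abs(v_new - v)) < 1e-14:
                v = v_new
                break
            v = v_new
        for node, val in zip(order, v):
            assert cent.loc[node, "pagerank"] == pytest.approx(val, abs=1e-8)


class TestSummaryStats:
    def test_triangle(self):
        edges = [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0)]
        net = _net_from_edges(edges)
        net.backbone_edges = net.edges
        out = summary_stats(net)
        assert out["clustering_coefficient"] == pytest.approx(1.0)
        assert out["diameter"] == pytest.approx(1.0)  # 1/weight lengths

    def test_path_p4(self):
        edges = [("a", "b", 1.0), ("b", "c", 1.0), ("c", "d", 1.0)]
        net = _net_from_edges(edges)
        net.backbone_edges = net.edges
        out = summary_stats(net)
        assert out["diameter"] == pytest.approx(3.0)
        assert out["average_path_length"] == pytest.approx(10.0 / 6.0)

    def test_empty(self):
        net = _net_from_edges([("a", "b", 1.0)])
        net.backbone_edges = net.edges.iloc[0:0]
        out = summary_stats(net)
        assert out["n_nodes"] == 0

    def test_er_vs_ba_scale_free_fit(self):
        er_r2, ba_r2 = [], []
        for seed in range(10):
            er = nx.gnm_random_graph(200, 600, seed=seed)
            ba = nx.barabasi_albert_graph(200, 3, seed=seed)
            er_r2.append(scale_free_fit(er))
            ba_r2.append(scale_free_fit(ba))
        assert np.mean(ba_r2) > np.mean(er_r2)


class TestModuleRecovery:
    def test_planted_modules_ari(self, small_cohort):
        from sklearn.metrics import adjusted_rand_score

        from omnileaf.synthdata import SimConfig, simulate_cohort
        from omnileaf.synthdata.config import ExprConfig

        cfg = SimConfig(
            n_geno=80, n_snp=30, n_gene=120, n_rep=2, seed=21,
            expr=ExprConfig(n_modules=4, module_size=30, n_deg=0,
                            module_loading=0.8),
        )
        _, _, expr, truth = simulate_cohort(cfg)
        adj = filter_and_adjust(expr.counts)
        score_sets = [infer(adj, m) for m in ("pearson", "spearman")]
        net = aggregate_irp(score_sets)
        net = backbone(net, sigma=2.32)
        labels = partition(net)
        true = pd.Series({g: truth.module_of.get(g, 0) for g in labels.index})
        assert len(labels) >= 100
        assert adjusted_rand_score(true[labels.index], labels) > 0.8
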