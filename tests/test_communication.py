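import numpy as np
import pandas as pd
import pytest

from pulpatlas.core_io import AnalysisConfig, LRDatabase, LRPair, log_normalize
from pulpatlas.communication import (
    CommNetwork,
    bootstrap_metrics,
    cluster_expression,
    communication_probability,
    delta_network,
    infer_network,
    network_summaries,
    pair_condition_delta,
)
from pulpatlas.synthetic_data import build_config, fixture_lr_db, simulate_atlas

from conftest import annotations, toy_matrix


class TestClusterExpression:
    def test_constant_expression_either_estimator(self):
        m = toy_matrix(np.full((6, 2), 2.0), lognorm=True)
        ann = annotations(["A"] * 6)
        for est in ("mean", "trimean"):
            assert cluster_expression(m, ann, ["g0"], "A", "X", est) == 2.0

    def test_trimean_vs_mean_hand_example(self):
        m = toy_matrix(np.array([[0.0], [0.0], [0.0], [4.0]]), lognorm=True)
        ann = annotations(["A"] * 4)
        assert cluster_expression(m, ann, ["g0"], "A", "X", "mean") == 1.0
        # linear-interpolation quantiles: Q1=0, med=0, Q3=1 -> trimean 0.25
        assert cluster_expression(m, ann, ["g0"], "A", "X", "trimean") == 0.25

    def test_subunits_combine_by_geometric_mean(self):
        m = toy_matrix(np.tile([[1.0, 4.0]], (5, 1)), lognorm=True)
        ann = annotations(["A"] * 5)
        assert cluster_expression(m, ann, ["g0", "g1"], "A", "X") == pytest.approx(2.0)


class TestProbability:
    def test_silent_partner_gives_zero(self):
        assert communication_probability(0.0, 3.0) == 0.0
        assert communication_probability(3.0, 0.0) == 0.0

    def test_half_saturation_and_worked_value(self):
        assert communication_probability(1.0, 0.5, kh=0.5) == pytest.approx(0.5)
        assert communication_probability(2.0, 1.0, kh=0.5) == pytest.approx(0.8)

    def test_monotone_and_bounded(self):
        L = np.linspace(0, 10, 50)
        p = communication_probability(L, 1.0)
        assert np.all(np.diff(p) > 0)
        assert np.all((p >= 0) & (p < 1))


@pytest.fixture(scope="module")
def planted_net(small_atlas):
    m, ann, gt, cfg = small_atlas
    lrdb = fixture_lr_db(cfg)
    acfg = AnalysisConfig(n_perm=100, seed=3)
    nets = {
        cond: infer_network(m, ann, lrdb, cond, acfg, seed=101)
        for cond in ("Healthy", "Advanced")
    }
    return m, ann, gt, lrdb, acfg, nets


class TestInferNetwork:
    def test_min_cells_excludes_small_clusters(self):
        vals = np.abs(np.random.default_rng(0).normal(1, 0.3, size=(24, 4)))
        m = toy_matrix(vals, lognorm=True)
        clusters = ["A"] * 10 + ["B"] * 10 + ["tiny"] * 4
        ann = annotations(clusters)
        lrdb = LRDatabase([LRPair("p1", ("g0",), ("g1",), "P")])
        net = infer_network(m, ann, lrdb, "X", AnalysisConfig(min_cells=5, n_perm=20))
        assert "tiny" not in net.clusters
        assert not (net.edges[["sender", "receiver"]] == "tiny").any().any()

    def test_no_cluster_passing_is_error(self):
        m = toy_matrix(np.ones((4, 2)), lognorm=True)
        ann = annotations(["A", "A", "B", "B"])
        lrdb = LRDatabase([LRPair("p1", ("g0",), ("g1",), "P")])
        with pytest.raises(ValueError, match="min_cells"):
            infer_network(m, ann, lrdb, "X", AnalysisConfig(min_cells=5, n_perm=10))

    def test_planted_edge_significant_and_top_ranked(self, planted_net):
        _, _, gt, _, _, nets = planted_net
        edges = nets["Healthy"].edges
        top = edges.sort_values("prob", ascending=False).iloc[0]
        planted = gt.planted_lr["P001"]
        assert (top["sender"], top["receiver"], top["pair"]) == (
            planted.sender,
            planted.receiver,
            "P001",
        )
        assert top["significant"]

    def test_pvalues_respect_permutation_floor(self, planted_net):
        _, _, _, _, acfg, nets = planted_net
        p = nets["Healthy"].edges["p"]
        assert (p >= 1 / (acfg.n_perm + 1) - 1e-12).all()
        assert (p <= 1.0).all()

    def test_edges_shrink_as_alpha_tightens(self, planted_net):
        _, _, _, _, _, nets = planted_net
        edges = nets["Healthy"].edges
        n_05 = (edges["p"] < 0.05).sum()
        n_01 = (edges["p"] < 0.01).sum()
        assert n_01 <= n_05


class TestSummaries:
    def test_empty_network_zeroes(self):
        edges = pd.DataFrame(
            columns=["sender", "receiver", "pair", "pathway", "prob", "p", "significant"]
        ).astype({"significant": bool, "prob": float})
        net = CommNetwork(condition="X", clusters=["A", "B"], edges=edges)
        s = network_summaries(net)
        assert (s.n_interactions, s.total_strength) == (0, 0.0)
        assert (s.counts.to_numpy() == 0).all()

    def test_three_edges_sum(self):
        edges = pd.DataFrame(
            {
                "sender": ["A", "A", "B"],
                "receiver": ["B", "B", "A"],
                "pair": ["p1", "p2", "p1"],
                "pathway": ["P", "P", "P"],
                "prob": [0.2, 0.3, 0.5],
                "p": [0.01] * 3,
                "significant": [True] * 3,
            }
        )
        s = network_summaries(CommNetwork("X", ["A", "B"], edges))
        assert s.n_interactions == 3
        assert s.total_strength == pytest.approx(1.0)
        assert s.pathway_strength["P"] == pytest.approx(1.0)

    def test_counts_matrix_marginals_match_edge_counts(self, planted_net):
        _, _, _, _, _, nets = planted_net
        net = nets["Healthy"]
        sig = net.significant_edges()
        for c in net.clusters:
            assert net.counts.loc[c].sum() == (sig["sender"] == c).sum()
            assert net.counts[c].sum() == (sig["receiver"] == c).sum()


class TestDelta:
    def test_never_significant_pair_excluded(self, planted_net):
        _, _, _, _, _, nets = planted_net
        d = pair_condition_delta(nets, "Healthy", "Advanced", mode="pair")
        sig_pairs = set(nets["Healthy"].significant_edges()["pair"]) | set(
            nets["Advanced"].significant_edges()["pair"]
        )
        assert set(d["pair"]) == sig_pairs

    def test_planted_decline_appears_in_decreasing_list(self, planted_net):
        _, _, _, _, _, nets = planted_net
        d = pair_condition_delta(nets, "Healthy", "Advanced", mode="pair")
        row = d[d["pair"] == "P001"]  # planted Healthy-only activity
        assert len(row) == 1 and row["delta"].iloc[0] < 0
        assert d["delta"].is_monotonic_increasing
        assert list(d["rank"]) == list(range(1, len(d) + 1))

    def test_identical_networks_zero_delta(self, planted_net):
        _, _, _, _, _, nets = planted_net
        net = nets["Healthy"]
        dmat, nodes = delta_network(net, net)
        assert (dmat.to_numpy() == 0).all()
        assert (nodes[["gained", "lost", "net"]].to_numpy() == 0).all()

    def test_single_new_edge_node_bookkeeping(self):
        cols = ["sender", "receiver", "pair", "pathway", "prob", "p", "significant"]
        base = pd.DataFrame(columns=cols).astype({"significant": bool, "prob": float})
        gained = pd.DataFrame(
            [["A", "B", "p1", "P", 0.5, 0.01, True]], columns=cols
        )
        n_from = CommNetwork("X", ["A", "B"], base)
        n_to = CommNetwork("X", ["A", "B"], gained)
        dmat, nodes = delta_network(n_from, n_to)
        got = nodes.set_index("cluster")["net"]
        assert got["A"] == 1 and got["B"] == 1
        assert dmat.loc["A", "B"] == pytest.approx(0.5)

    def test_matches_brute_force_edge_set_difference(self, planted_net):
        _, _, _, _, _, nets = planted_net
        dmat, nodes = delta_network(nets["Healthy"], nets["Advanced"])

        def keyset(net):
            sig = net.significant_edges()
            return set(zip(sig["sender"], sig["receiver"], sig["pair"]))

        kh, ka = keyset(nets["Healthy"]), keyset(nets["Advanced"])
        for row in nodes.itertuples():
            g = sum((s == row.cluster) + (r == row.cluster) for s, r, _ in ka - kh)
            l = sum((s == row.cluster) + (r == row.cluster) for s, r, _ in kh - ka)
            assert row.net == g - l


class TestBootstrap:
    def test_degenerate_all_zero_probs(self):
        # ligand gene silent everywhere -> every prob 0 -> CI [0,0]
        vals = np.ones((20, 2))
        vals[:, 0] = 0.0
        m = toy_matrix(vals, lognorm=True)
        ann = annotations(["A"] * 10 + ["B"] * 10)
        lrdb = LRDatabase([LRPair("p1", ("g0",), ("g1",), "P")])
        out = bootstrap_metrics(
            m, ann, lrdb, "X", AnalysisConfig(n_perm=20, n_boot=30, seed=1)
        )
        for s in out.values():
            assert (s.ci_low, s.point, s.ci_high) == (0.0, 0.0, 0.0)

    def test_ci_brackets_point(self, planted_net):
        m, ann, _, lrdb, _, _ = planted_net
        cfg = AnalysisConfig(n_perm=30, n_boot=40, seed=5)
        out = bootstrap_metrics(m, ann, lrdb, "Healthy", cfg)
        for s in out.values():
            assert s.ci_low <= s.point <= s.ci_high
            assert s.n_boot == 40

    def test_seed_deterministic(self, planted_net):
        m, ann, _, lrdb, _, _ = planted_net
        cfg = AnalysisConfig(n_perm=10, n_boot=10, seed=9)
        a = bootstrap_metrics(m, ann, lrdb, "Healthy", cfg)
        b = bootstrap_metrics(m, ann, lrdb, "Healthy", cfg)
        for k in a:
            assert (a[k].point, a[k].ci_low, a[k].ci_high) == (
                b[k].point,
                b[k].ci_low,
                b[k].ci_high,
            )
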