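import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clpnet.centrality import (COGNITION_CLUSTER, SYMPTOM_CLUSTER,
                               CentralityError, ClusterAssignment, bridge_ei1,
                               bridge_ei2, centrality_table, in_prediction,
                               out_prediction)
from clpnet.clpn import TemporalNetwork, estimate_temporal
from clpnet.ggm import EstimationConfig, estimate_contemporaneous
from clpnet.synthetic import SimTruth, simulate_panel

from conftest import toy_network


def _tnet(B, labels):
    return TemporalNetwork(B=B, node_labels=labels, selections=(),
                           n_used=100, gamma=0.5)


class TestClusterAssignment:
    def test_from_roles(self, schema, clusters):
        assert clusters.cluster_of("dep") == SYMPTOM_CLUSTER
        assert clusters.cluster_of("ps") == COGNITION_CLUSTER
        assert clusters.cluster_of("age") is None

    def test_requires_both_clusters(self):
        with pytest.raises(CentralityError):
            ClusterAssignment({"a": SYMPTOM_CLUSTER, "b": SYMPTOM_CLUSTER})

    def test_unknown_node(self, clusters):
        with pytest.raises(CentralityError):
            clusters.cluster_of("nope")


class TestBridgeEI1:
    def test_hand_values(self, toy_bridge_fixture):
        net, cl = toy_bridge_fixture
        assert bridge_ei1(net, cl, "A") == pytest.approx(0.3)
        assert bridge_ei1(net, cl, "B") == pytest.approx(-0.2)
        assert bridge_ei1(net, cl, "C") == pytest.approx(0.1)

    def test_no_cross_edges_zero(self):
        net, cl = toy_network(a_c=0.0, b_c=0.0, a_b=0.5)
        assert bridge_ei1(net, cl, "A") == 0.0

    def test_covariate_raises(self, complete_panel, clusters):
        net = estimate_contemporaneous(complete_panel.dataset, "w1",
                                       EstimationConfig(n_lambda=20))
        with pytest.raises(CentralityError):
            bridge_ei1(net, clusters, "age")

    @settings(max_examples=30, deadline=None)
    @given(st.floats(-0.5, 0.5), st.floats(-0.5, 0.5), st.floats(-0.5, 0.5))
    def test_negation_linearity(self, a_c, b_c, a_b):
        net, cl = toy_network(a_c, b_c, a_b)
        neg, _ = toy_network(-a_c, -b_c, -a_b)
        # one-step bridge EI is linear in the weights (the two-step variant
        # is not: its propagation term is quadratic)
        for node in ("A", "B", "C"):
            assert bridge_ei1(neg, cl, node) == pytest.approx(
                -bridge_ei1(net, cl, node))

    def test_cross_cluster_sum_identity(self, complete_panel, clusters):
        net = estimate_contemporaneous(complete_panel.dataset, "w1",
                                       EstimationConfig(n_lambda=30))
        sym = [n for n in net.node_labels if clusters.cluster_of(n) == SYMPTOM_CLUSTER]
        cog = [n for n in net.node_labels if clusters.cluster_of(n) == COGNITION_CLUSTER]
        s1 = sum(bridge_ei1(net, clusters, n) for n in sym)
        s2 = sum(bridge_ei1(net, clusters, n) for n in cog)
        assert s1 == pytest.approx(s2, abs=1e-10)


class TestBridgeEI2:
    def test_hand_value(self, toy_bridge_fixture):
        net, cl = toy_bridge_fixture
        # 0.3 + 0.5*(-0.2) + 0.3*0.1
        assert bridge_ei2(net, cl, "A") == pytest.approx(0.23)

    def test_empty_network_zero(self):
        net, cl = toy_network(0.0, 0.0, 0.0)
        for node in ("A", "B", "C"):
            assert bridge_ei1(net, cl, node) == 0.0
            assert bridge_ei2(net, cl, node) == 0.0

    def test_star_graph_leaf(self):
        # only the hub B has a cross-cluster edge; leaf A touches just B
        net, cl = toy_network(a_c=0.0, b_c=0.4, a_b=0.25)
        hub_ei1 = bridge_ei1(net, cl, "B")
        assert bridge_ei2(net, cl, "A") == pytest.approx(0.25 * hub_ei1)

    def test_equals_ei1_when_neighbors_have_zero_bridge(self):
        # bridging edge only: A-C; B isolated -> ei2(A) adds a_c * ei1(C)
        net, cl = toy_network(a_c=0.3, b_c=0.0, a_b=0.0)
        assert bridge_ei1(net, cl, "B") == 0.0
        # A's only neighbor is C with ei1(C)=0.3 (into {A,B}); construct the
        # stated degenerate case instead with zero bridging-neighbor values
        net2, cl2 = toy_network(a_c=0.0, b_c=0.0, a_b=0.6)
        for node in ("A", "B", "C"):
            assert bridge_ei2(net2, cl2, node) == bridge_ei1(net2, cl2, node)


class TestPredictions:
    def test_no_cross_entries_all_zero(self, complete_panel, clusters):
        labels = complete_panel.dataset.variable_names
        tnet = _tnet(0.5 * np.eye(13), labels)
        for node in ("dep", "ps", "wm"):
            assert in_prediction(tnet, complete_panel.dataset, clusters, node) == 0.0
            assert out_prediction(tnet, complete_panel.dataset, clusters, node) == 0.0

    def test_out_prediction_sum_of_squares(self, complete_panel, clusters):
        labels = complete_panel.dataset.variable_names
        B = np.zeros((13, 13))
        i = labels.index("som")
        B[i, labels.index("ps")] = 0.3
        B[i, labels.index("wm")] = 0.4
        B[i, labels.index("dep")] = 0.9  # same cluster: ignored
        tnet = _tnet(B, labels)
        assert out_prediction(tnet, complete_panel.dataset, clusters, "som") == \
            pytest.approx(0.25)

    def test_planted_lag_prediction(self, schema, clusters):
        names = [v.name for v in schema]
        som, ps = names.index("som"), names.index("ps")
        B = np.zeros((13, 13))
        B[som, ps] = -0.3
        truth = SimTruth(omega=np.eye(13), B_true=B, noise_sd=np.ones(13),
                         missing_rate=0.0, seed=9)
        truth.noise_sd[ps] = np.sqrt(1 - 0.09)
        res = simulate_panel(truth, 20_000, schema, seed=9)
        tnet = estimate_temporal(res.dataset)
        assert in_prediction(tnet, res.dataset, clusters, "ps") == \
            pytest.approx(0.09, abs=0.015)
        assert out_prediction(tnet, res.dataset, clusters, "som") == \
            pytest.approx(0.09, abs=0.015)

    def test_noise_predictors_with_zero_coef_ignored(self, complete_panel, clusters):
        labels = complete_panel.dataset.variable_names
        B = np.zeros((13, 13))
        B[labels.index("som"), labels.index("ps")] = -0.2
        tnet = _tnet(B, labels)
        base = in_prediction(tnet, complete_panel.dataset, clusters, "ps")
        # zero coefficients elsewhere: restriction ignores them by contract
        assert base == in_prediction(tnet, complete_panel.dataset, clusters, "ps")
        assert 0.0 <= base <= 1.0

    def test_relabel_invariance(self, complete_panel, clusters):
        ds = complete_panel.dataset
        tnet = estimate_temporal(ds, EstimationConfig(n_lambda=20))
        perm = np.random.default_rng(3).permutation(13)
        ds_p = ds.copy()
        ds_p = type(ds)(ds.values[:, perm, :],
                        tuple(np.array(ds.variables, dtype=object)[perm]))
        tnet_p = estimate_temporal(ds_p, EstimationConfig(n_lambda=20))
        for node in ("dep", "wm"):
            assert in_prediction(tnet_p, ds_p, clusters, node) == pytest.approx(
                in_prediction(tnet, ds, clusters, node), abs=1e-8)
            assert out_prediction(tnet_p, ds_p, clusters, node) == pytest.approx(
                out_prediction(tnet, ds, clusters, node), abs=1e-8)


class TestCentralityTable:
    def test_covariates_blank(self, complete_panel, clusters):
        cfg = EstimationConfig(n_lambda=20)
        cnet = estimate_contemporaneous(complete_panel.dataset, "w1", cfg)
        tnet = estimate_temporal(complete_panel.dataset, cfg)
        table = centrality_table(cnet, tnet, complete_panel.dataset, clusters)
        cov = table[table.node.isin(["age", "meno", "e2", "fsh"])]
        assert cov[["bridge_ei1", "bridge_ei2", "in_prediction",
                    "out_prediction"]].isna().all().all()
        rest = table[~table.node.isin(["age", "meno", "e2", "fsh"])]
        assert rest["in_prediction"].between(0, 1).all()
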