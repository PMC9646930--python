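import numpy as np
import pytest

from clpnet.data_model import PanelDataset, VariableSpec
from clpnet.ggm import (ContemporaneousNetwork, EstimationConfig,
                        EstimationError, correlation_matrix, ebic,
                        estimate_contemporaneous, glasso_fit, lambda_path,
                        restricted_mle)
from clpnet.synthetic import SimTruth, make_truth, simulate_panel

from _oracles import admm_glasso, partial_correlations_from_inverse

V2 = (VariableSpec("a", "symptom", -1e6, 1e6),
      VariableSpec("b", "cognition", -1e6, 1e6))


def _panel(X: np.ndarray, schema) -> PanelDataset:
    values = np.stack([X, X], axis=2)
    return PanelDataset(values, schema)


def _sparse_corr_4() -> np.ndarray:
    omega = np.array([[1.5, 0.4, 0.0, 0.0],
                      [0.4, 1.5, 0.3, 0.0],
                      [0.0, 0.3, 1.5, 0.2],
                      [0.0, 0.0, 0.2, 1.5]])
    sigma = np.linalg.inv(omega)
    d = np.sqrt(np.diag(sigma))
    return sigma / np.outer(d, d)


class TestCorrelationMatrix:
    def test_perfect_correlation(self):
        x = np.linspace(0, 1, 50)
        ds = _panel(np.column_stack([x, 2 * x + 1]), V2)
        S = correlation_matrix(ds, "w1")
        assert S[0, 1] == pytest.approx(1.0)

    def test_constant_column_raises(self):
        ds = _panel(np.column_stack([np.ones(10), np.arange(10.0)]), V2)
        with pytest.raises(EstimationError, match="'a'"):
            correlation_matrix(ds, "w1")

    def test_incomplete_raises(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        ds = _panel(X, V2)
        ds.values[0, 0, 0] = np.nan
        with pytest.raises(EstimationError, match="complete"):
            correlation_matrix(ds, "w1")

    def test_independent_columns_small_r(self):
        X = np.random.default_rng(1).normal(size=(100_000, 2))
        S = correlation_matrix(_panel(X, V2), "w1")
        assert abs(S[0, 1]) < 0.02

    def test_spearman_rank_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(500, 2))
        x[:, 1] = 0.8 * x[:, 0] + 0.6 * x[:, 1]
        mono = np.column_stack([np.exp(x[:, 0]), x[:, 1]])
        s_raw = correlation_matrix(_panel(x, V2), "w1", "spearman")[0, 1]
        s_tr = correlation_matrix(_panel(mono, V2), "w1", "spearman")[0, 1]
        p_raw = correlation_matrix(_panel(x, V2), "w1", "pearson")[0, 1]
        p_tr = correlation_matrix(_panel(mono, V2), "w1", "pearson")[0, 1]
        assert s_raw == pytest.approx(s_tr, abs=1e-12)
        assert abs(p_raw - p_tr) > 0.01

    def test_properties(self, complete_panel):
        S = correlation_matrix(complete_panel.dataset, "w1")
        assert np.allclose(S, S.T)
        assert np.allclose(np.diag(S), 1.0)
        assert np.linalg.eigvalsh(S).min() > -1e-8


class TestGlassoFit:
    def test_full_shrinkage(self):
        S = _sparse_corr_4()
        lam = np.abs(S - np.eye(4)).max()
        theta = glasso_fit(S, lam)
        off = theta - np.diag(np.diag(theta))
        assert np.all(off == 0)

    def test_bivariate_identity(self):
        S = np.array([[1.0, 0.5], [0.5, 1.0]])
        theta = glasso_fit(S, 0.0)
        pcor = -theta[0, 1] / np.sqrt(theta[0, 0] * theta[1, 1])
        assert pcor == pytest.approx(0.5, abs=1e-6)

    @pytest.mark.parametrize("lam", [0.01, 0.05, 0.2])
    def test_matches_admm_oracle(self, lam):
        S = _sparse_corr_4()
        theta = glasso_fit(S, lam, tol=1e-7)
        oracle = admm_glasso(S, lam)
        assert np.abs(theta - oracle).max() < 1e-4

    def test_exact_zeros(self):
        S = _sparse_corr_4()
        theta = glasso_fit(S, 0.1)
        off = theta[np.triu_indices(4, 1)]
        assert np.any(off == 0.0)  # soft thresholding produces exact zeros

    def test_asymmetric_raises(self):
        S = np.array([[1.0, 0.5], [0.4, 1.0]])
        with pytest.raises(EstimationError, match="symmetric"):
            glasso_fit(S, 0.1)

    def test_negative_lambda_raises(self):
        with pytest.raises(ValueError):
            glasso_fit(np.eye(2), -0.1)

    def test_restricted_mle_reproduces_inverse(self):
        S = _sparse_corr_4()
        theta = restricted_mle(S, np.ones((4, 4), dtype=bool))
        assert np.abs(theta - np.linalg.inv(S)).max() < 1e-4


class TestEbic:
    def test_hand_value(self):
        assert ebic(np.eye(2), np.eye(2), 100, 0.5) == pytest.approx(200.0)
        assert ebic(np.eye(2), np.eye(2), 100, 0.0) == pytest.approx(200.0)

    def test_gamma_zero_is_bic(self):
        S = _sparse_corr_4()
        theta = glasso_fit(S, 0.05)
        E = np.count_nonzero(theta[np.triu_indices(4, 1)])
        sign, logdet = np.linalg.slogdet(theta)
        bic = -100 * (logdet - np.trace(S @ theta)) + E * np.log(100)
        assert ebic(theta, S, 100, 0.0) == pytest.approx(bic)

    def test_diagonal_theta_pure_deviance(self):
        theta = np.diag([2.0, 0.5, 1.0])
        S = _sparse_corr_4()[:3, :3]
        sign, logdet = np.linalg.slogdet(theta)
        dev = -50 * (logdet - np.trace(S @ theta))
        assert ebic(theta, S, 50, 0.7) == pytest.approx(dev)

    def test_non_pd_raises(self):
        with pytest.raises(EstimationError):
            ebic(np.diag([1.0, -1.0]), np.eye(2), 100, 0.5)


class TestEstimateContemporaneous:
    def test_network_invariants(self, complete_panel):
        net = estimate_contemporaneous(complete_panel.dataset, "w1")
        assert np.allclose(net.pcor, net.pcor.T)
        assert np.all(np.diag(net.pcor) == 0)
        assert np.abs(net.pcor).max() < 1
        assert len(net.ebic_path) == 100
        # edge counts monotone non-increasing as lambda increases
        assert np.all(np.diff(net.edge_counts) >= 0)  # path is descending

    def test_degenerate_two_point_path(self, complete_panel):
        cfg = EstimationConfig(n_lambda=2)
        net = estimate_contemporaneous(complete_panel.dataset, "w1", cfg)
        assert len(net.ebic_path) == 2
        assert net.lambda_selected in net.lambda_path

    def test_lambda_zero_limit_matches_closed_form(self, wide_schema):
        truth = make_truth(seed=31, density=0.3, effect_range=(0.2, 0.4),
                           missing_rate=0.0)
        res = simulate_panel(truth, 5000, wide_schema, seed=31)
        S = correlation_matrix(res.dataset, "w1")
        theta = glasso_fit(S, 0.0, tol=1e-9)
        d = np.sqrt(np.diag(theta))
        pcor = -theta / np.outer(d, d)
        np.fill_diagonal(pcor, 0.0)
        assert np.abs(pcor - partial_correlations_from_inverse(S)).max() < 1e-3

    def test_permutation_invariance(self, wide_schema):
        truth = make_truth(seed=33, density=0.2, missing_rate=0.0)
        res = simulate_panel(truth, 800, wide_schema, seed=33)
        cfg = EstimationConfig(n_lambda=30, tol=1e-10)
        net = estimate_contemporaneous(res.dataset, "w1", cfg)
        perm = np.random.default_rng(0).permutation(13)
        permuted = PanelDataset(res.dataset.values[:, perm, :],
                                tuple(np.array(res.dataset.variables,
                                               dtype=object)[perm]))
        net_p = estimate_contemporaneous(permuted, "w1", cfg)
        inv = np.argsort(perm)
        assert np.abs(net_p.pcor[np.ix_(inv, inv)] - net.pcor).max() < 1e-8

    def test_identity_precision_specificity(self, wide_schema):
        spurious = []
        for s in range(5):
            truth = make_truth(seed=200 + s, density=0.0, missing_rate=0.0)
            res = simulate_panel(truth, 2000, wide_schema, seed=300 + s)
            net = estimate_contemporaneous(res.dataset, "w1")
            spurious.append(net.n_edges)
        assert sum(e <= 1 for e in spurious) >= 4

    def test_selection_records_path(self, complete_panel):
        net = estimate_contemporaneous(complete_panel.dataset, "w1")
        best = int(np.argmin(net.ebic_path))
        assert net.lambda_selected == net.lambda_path[best]


def test_lambda_path_shape():
    S = _sparse_corr_4()
    path = lambda_path(S, 100, 0.01)
    assert len(path) == 100
    assert path[0] == pytest.approx(np.abs(S - np.eye(4)).max())
    assert path[-1] == pytest.approx(path[0] * 0.01)
    assert np.all(np.diff(path) < 0)
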