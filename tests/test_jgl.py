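"""Joint graphical lasso: oracle equivalences, limits, model selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from synovnet.jgl import (JGLConfig, differential_clusters, group_covariances,
                          joint_graphical_lasso, model_selection, nearest_psd)


def _random_cov(rng, p, strength=1.0):
    A = rng.normal(size=(p, p))
    return A @ A.T / p + strength * np.eye(p)


TIGHT = dict(tol_primal=1e-9, tol_dual=1e-9, max_iter=20000)


class TestSolverOracles:
    def test_unpenalized_recovers_inverse_covariance(self):
        rng = np.random.default_rng(0)
        S = _random_cov(rng, 8)
        est = joint_graphical_lasso(
            [S], [40], JGLConfig(lambda1=0.0, lambda2=0.0, **TIGHT))
        assert est.converged
        np.testing.assert_allclose(est.theta[0], np.linalg.inv(S), atol=1e-6)

    def test_two_group_unpenalized(self):
        rng = np.random.default_rng(1)
        S1, S2 = _random_cov(rng, 6), _random_cov(rng, 6)
        est = joint_graphical_lasso(
            [S1, S2], [30, 20], JGLConfig(lambda1=0.0, lambda2=0.0, **TIGHT))
        np.testing.assert_allclose(est.theta[0], np.linalg.inv(S1), atol=1e-6)
        np.testing.assert_allclose(est.theta[1], np.linalg.inv(S2), atol=1e-6)

    def test_zero_fusion_equals_independent_single_group_runs(self):
        """lambda2 = 0 decouples the groups: the joint fit equals two
        single-group runs of the same solver to 1e-6 Frobenius."""
        rng = np.random.default_rng(2)
        S1, S2 = _random_cov(rng, 7), _random_cov(rng, 7)
        cfg = JGLConfig(lambda1=3.0, lambda2=0.0, **TIGHT)
        joint = joint_graphical_lasso([S1, S2], [25, 35], cfg)
        for k, (S, n) in enumerate([(S1, 25), (S2, 35)]):
            single = joint_graphical_lasso([S], [n], cfg)
            gap = np.linalg.norm(joint.theta[k] - single.theta[0], "fro")
            assert gap < 1e-6

    def test_matches_sklearn_graphical_lasso(self):
        """Independent cross-check: single-group solution agrees with
        scikit-learn's graphical lasso at the matching per-observation
        penalty."""
        from sklearn.covariance import GraphicalLasso

        rng = np.random.default_rng(3)
        S = _random_cov(rng, 6)
        n, lam1 = 50, 2.5
        est = joint_graphical_lasso([S], [n], JGLConfig(lambda1=lam1, lambda2=0.0,
                                                        **TIGHT))
        gl = GraphicalLasso(alpha=lam1 / n, covariance="precomputed",
                            tol=1e-12, max_iter=2000).fit(S)
        np.testing.assert_allclose(est.theta[0], gl.precision_, atol=5e-5)

    def test_p2_closed_form_soft_threshold(self):
        """For p = 2, K = 1 the estimated covariance off-diagonal is the
        soft-thresholded sample covariance, sign(s12) max(|s12| - lambda1/n, 0);
        verified against direct minimisation of the objective."""
        n = 30
        for s12 in (-0.6, -0.2, 0.05, 0.4, 0.8):
            for lam1 in (0.5, 3.0, 9.0, 40.0):
                S = np.array([[1.0, s12], [s12, 1.0]])
                est = joint_graphical_lasso(
                    [S], [n], JGLConfig(lambda1=lam1, lambda2=0.0, **TIGHT))
                sigma = np.linalg.inv(est.theta[0])
                want = np.sign(s12) * max(abs(s12) - lam1 / n, 0.0)
                assert sigma[0, 1] == pytest.approx(want, abs=2e-5)

                # independent oracle: minimise the objective directly over
                # (log-diagonal, off-diagonal) parameterisation of Theta
                def obj(params):
                    d1, d2, o = params
                    theta = np.array([[np.exp(d1), o], [o, np.exp(d2)]])
                    sign, logdet = np.linalg.slogdet(theta)
                    if sign <= 0:
                        return 1e10
                    return (n * (np.sum(S * theta) - logdet)
                            + lam1 * 2 * abs(o))

                best = min(
                    (minimize(obj, x0, method="Nelder-Mead",
                              options={"xatol": 1e-10, "fatol": 1e-12,
                                       "maxiter": 5000})
                     for x0 in ([0.0, 0.0, 0.0], [0.5, 0.5, -0.3],
                                [0.5, 0.5, 0.3])),
                    key=lambda r: r.fun,
                )
                theta_direct = np.array(
                    [[np.exp(best.x[0]), best.x[2]],
                     [best.x[2], np.exp(best.x[1])]])
                np.testing.assert_allclose(
                    est.theta[0], theta_direct, atol=5e-4)

    def test_huge_sparsity_penalty_empties_adjacency(self):
        rng = np.random.default_rng(4)
        S1, S2 = _random_cov(rng, 6), _random_cov(rng, 6)
        est = joint_graphical_lasso(
            [S1, S2], [30, 30], JGLConfig(lambda1=1e5, lambda2=0.0))
        assert est.edge_count(0) == 0 and est.edge_count(1) == 0

    def test_huge_fusion_forces_equal_precisions(self):
        rng = np.random.default_rng(5)
        S1, S2 = _random_cov(rng, 6), _random_cov(rng, 6, strength=2.0)
        est = joint_graphical_lasso(
            [S1, S2], [30, 30],
            JGLConfig(lambda1=1.0, lambda2=1e4, admm_rho=50.0, max_iter=20000,
                      tol_primal=1e-8, tol_dual=1e-8))
        assert np.abs(est.theta[0] - est.theta[1]).max() < 1e-4


class TestSolverProperties:
    def test_objective_non_increasing(self):
        rng = np.random.default_rng(6)
        for strength, lam1, lam2 in [(1.0, 0.5, 0.2), (0.5, 2.0, 1.0),
                                     (2.0, 5.0, 0.0)]:
            S1 = _random_cov(rng, 10, strength)
            S2 = _random_cov(rng, 10, strength)
            est = joint_graphical_lasso(
                [S1, S2], [20, 25], JGLConfig(lambda1=lam1, lambda2=lam2))
            diffs = np.diff(est.objective_trace)
            assert (diffs <= 1e-8).all()

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(7)
        S1, S2 = _random_cov(rng, 8), _random_cov(rng, 8)
        perm = rng.permutation(8)
        cfg = JGLConfig(lambda1=2.0, lambda2=0.5, **TIGHT)
        est = joint_graphical_lasso([S1, S2], [25, 25], cfg)
        est_p = joint_graphical_lasso(
            [S1[np.ix_(perm, perm)], S2[np.ix_(perm, perm)]], [25, 25], cfg)
        for k in range(2):
            np.testing.assert_allclose(
                est_p.theta[k], est.theta[k][np.ix_(perm, perm)], atol=1e-6)

    def test_edges_monotone_in_lambda1_on_grid(self):
        rng = np.random.default_rng(8)
        S1, S2 = _random_cov(rng, 8), _random_cov(rng, 8)
        counts = []
        for lam1 in (0.5, 2.0, 8.0, 32.0):
            est = joint_graphical_lasso(
                [S1, S2], [30, 30], JGLConfig(lambda1=lam1, lambda2=0.2))
            counts.append(est.edge_count(0) + est.edge_count(1))
        # strict monotonicity is not guaranteed in general; report-only check
        violations = sum(b > a for a, b in zip(counts, counts[1:]))
        assert violations == 0, f"edge counts increased along grid: {counts}"

    def test_asymmetric_input_rejected(self):
        S = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            joint_graphical_lasso([S], [10], JGLConfig())


class TestModelSelection:
    def test_single_grid_point_selected(self):
        rng = np.random.default_rng(9)
        S1, S2 = _random_cov(rng, 5), _random_cov(rng, 5)
        table, fits = model_selection([S1, S2], [20, 20], [1.0], [0.1])
        assert len(table) == 1
        assert set(table["selected"].iloc[0].split("+")) == {"bic", "aic", "dense"}

    def test_planted_structure_recovery(self):
        """p=20, 10 shared + 5 per-group edges, n=100/group: the BIC model
        recovers most planted edges with a bounded false-discovery
        proportion (median over 50 replicates).

        The grid spans per-observation penalties lambda1/n in [0.3, 0.9],
        the sqrt(log p / n) scale appropriate for standardized data at
        n = 100 (below that scale, BIC on shrunken-likelihood lasso fits is
        known to over-select)."""
        from synovnet.simulate import chain_precision

        shared = [(i, i + 1) for i in range(10)]
        extra1 = [(11, 12), (12, 13), (13, 14), (14, 15), (15, 16)]
        extra2 = [(11, 13), (12, 14), (16, 18), (17, 19), (15, 17)]
        theta1 = chain_precision(20, shared + extra1, weight=0.35)
        theta2 = chain_precision(20, shared + extra2, weight=0.35)
        sig1, sig2 = np.linalg.inv(theta1), np.linalg.inv(theta2)
        rng = np.random.default_rng(10)
        recalls, fdps = [], []
        for _ in range(50):
            X1 = rng.multivariate_normal(np.zeros(20), sig1, size=100)
            X2 = rng.multivariate_normal(np.zeros(20), sig2, size=100)
            S1, S2 = np.cov(X1.T, bias=True), np.cov(X2.T, bias=True)
            table, fits = model_selection(
                [S1, S2], [100, 100], [30.0, 45.0, 60.0, 90.0], [0.0, 2.0])
            est = fits["bic"]
            true_edges = [set(map(frozenset, shared + extra1)),
                          set(map(frozenset, shared + extra2))]
            got, hit, false = 0, 0, 0
            for k in range(2):
                ii, jj = np.nonzero(np.triu(est.adjacency[k], 1))
                found = {frozenset((a, b)) for a, b in zip(ii, jj)}
                got += len(found)
                hit += len(found & true_edges[k])
                false += len(found - true_edges[k])
            recalls.append(hit / 30)
            fdps.append(false / max(got, 1))
        assert np.median(recalls) >= 0.7
        assert np.median(fdps) <= 0.3

    def test_denser_model_has_lower_aic_when_fit_strictly_better(self):
        # at lambda1 ~ 0 fit dominates; AIC of the dense model beats the
        # heavily penalised sparse one on correlated data
        rng = np.random.default_rng(11)
        S = nearest_psd(np.full((6, 6), 0.5) + 0.5 * np.eye(6))
        table, _ = model_selection([S, S], [40, 40], [0.01, 80.0], [0.0])
        aic = table.set_index("lambda1")["aic"]
        assert aic[0.01] < aic[80.0]


class TestClusters:
    def _estimate(self, adj1, adj2):
        from synovnet.jgl import PrecisionEstimate

        p = adj1.shape[0]
        return PrecisionEstimate(
            theta=[np.eye(p), np.eye(p)], adjacency=[adj1, adj2],
            iterations=1, primal_residual=0.0, dual_residual=0.0,
            converged=True, n_list=[10, 10], S_list=[np.eye(p), np.eye(p)],
            config=JGLConfig())

    def test_identical_adjacencies_no_clusters(self):
        adj = np.zeros((4, 4), bool)
        adj[0, 1] = adj[1, 0] = True
        out = differential_clusters(self._estimate(adj, adj.copy()))
        assert out == {"control": [], "OA": []}

    def test_control_only_chain_is_one_cluster(self):
        adj1 = np.zeros((5, 5), bool)
        for i, j in [(0, 1), (1, 2)]:
            adj1[i, j] = adj1[j, i] = True
        adj2 = np.zeros((5, 5), bool)
        out = differential_clusters(self._estimate(adj1, adj2),
                                    names=list("abcde"))
        assert out["control"] == [["a", "b", "c"]]
        assert out["OA"] == []

    def test_planted_block_recovered_end_to_end(self):
        from synovnet.simulate import chain_precision

        rng = np.random.default_rng(12)
        theta1 = chain_precision(8, [(0, 1), (1, 2), (2, 3)], weight=0.45)
        theta2 = chain_precision(8, [], weight=0.45)
        X1 = rng.multivariate_normal(np.zeros(8), np.linalg.inv(theta1), 300)
        X2 = rng.multivariate_normal(np.zeros(8), np.linalg.inv(theta2), 300)
        # lambda1/n ~ 0.27, the sqrt(log p / n) scale for n = 300
        est = joint_graphical_lasso(
            [np.cov(X1.T, bias=True), np.cov(X2.T, bias=True)], [300, 300],
            JGLConfig(lambda1=80.0, lambda2=0.0))
        out = differential_clusters(est, names=list("abcdefgh"))
        assert out["control"] == [["a", "b", "c", "d"]]
        assert out["OA"] == []


def test_group_covariances_pairwise_complete_and_psd():
    rng = np.random.default_rng(13)
    mat = rng.normal(size=(30, 6))
    mat[rng.random(mat.shape) < 0.15] = np.nan
    df = pd.DataFrame(mat, columns=[f"P{i}" for i in range(6)])
    groups = ["control"] * 15 + ["OA"] * 15
    S_list, n_list, names = group_covariances(df, groups)
    assert n_list == [15, 15]
    for S in S_list:
        assert np.linalg.eigvalsh(S).min() >= -1e-12
        np.testing.assert_allclose(S, S.T, atol=1e-12)
    # complete-data case matches numpy covariance exactly
    full = pd.DataFrame(rng.normal(size=(20, 4)))
    full.columns = [f"Q{i}" for i in range(4)]
    S_list2, _, _ = group_covariances(full, ["control"] * 10 + ["OA"] * 10)
    np.testing.assert_allclose(
        S_list2[0], np.cov(full.iloc[:10].T, bias=True), atol=1e-12)
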