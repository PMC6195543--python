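"""EM mixture clustering: update equations, convergence, model selection."""

import numpy as np
import pytest

from mutclust.dag import Dag
from mutclust.mixture_em import (
    MixtureModel,
    aic,
    ari,
    best_of_restarts,
    em_fit,
    em_init,
    em_with_structure,
    finalize_clusters,
    hard_assignment,
    loglik_empty,
    nmi,
    select_k,
    select_chi,
    update_responsibilities,
    update_tau,
    update_theta,
)
from mutclust.predictive_scoring import classify
from mutclust.synthetic_data import (
    bernoulli_mixture_truth,
    opposing_dependence_truth,
    sample_mixture,
)


class TestUpdates:
    def test_tau_worked_example(self):
        T = np.array([[1.0, 0.0], [1.0, 0.0]])
        assert update_tau(T, 1.0) == pytest.approx([3 / 4, 1 / 4])

    def test_tau_uniform_input(self):
        T = np.full((10, 4), 0.25)
        assert update_tau(T, 2.0) == pytest.approx(np.full(4, 0.25))

    def test_tau_matches_formula(self, rng):
        T = rng.dirichlet(np.ones(3), size=20)
        chi = 0.7
        expect = (chi + T.sum(0)) / (chi * 3 + 20)
        assert update_tau(T, chi) == pytest.approx(expect)

    def test_theta_worked_example(self):
        D = np.array([[1], [1], [0]])
        T = np.ones((3, 1))
        assert update_theta(D, T, 1.0)[0, 0] == pytest.approx(2.5 / 4)

    def test_theta_empty_cluster_shrinks_to_half(self):
        D = np.array([[1], [0]])
        T = np.array([[1.0, 0.0], [1.0, 0.0]])
        T[:, 1] = 1e-12
        assert update_theta(D, T, 1.0)[0, 1] == pytest.approx(0.5, abs=1e-6)

    def test_theta_matches_formula(self, rng):
        D = (rng.random((15, 4)) < 0.4).astype(int)
        T = rng.dirichlet(np.ones(2), size=15)
        chi = 1.5
        expect = (chi / 2 + D.T @ T) / (chi + T.sum(0))
        assert update_theta(D, T, chi) == pytest.approx(expect)

    def test_loglik_all_half(self):
        D = np.array([[1, 0, 1, 1]])
        theta = np.full((4, 1), 0.5)
        assert loglik_empty(D, theta)[0, 0] == pytest.approx(4 * np.log(0.5))

    def test_loglik_single_gene(self):
        assert loglik_empty(np.array([[1]]), np.array([[0.7]]))[0, 0] == pytest.approx(np.log(0.7))

    def test_responsibilities_k1(self):
        L = np.array([[-3.0], [-1.0]])
        assert update_responsibilities(L, np.array([1.0])) == pytest.approx(np.ones((2, 1)))

    def test_responsibilities_identical_clusters_return_tau(self):
        L = np.tile(np.array([[-2.0]]), (5, 3))
        tau = np.array([0.5, 0.3, 0.2])
        T = update_responsibilities(L, tau)
        assert T == pytest.approx(np.tile(tau, (5, 1)))

    def test_responsibilities_match_formula(self, rng):
        L = rng.normal(-5, 2, size=(10, 3))
        tau = rng.dirichlet(np.ones(3))
        T = update_responsibilities(L, tau)
        expect = tau * np.exp(L)
        expect /= expect.sum(1, keepdims=True)
        assert T == pytest.approx(expect)


class TestEmInit:
    def test_zero_epsilon_is_uniform(self):
        T = em_init(5, 3, seed=0, epsilon=0.0).T
        assert T == pytest.approx(np.full((5, 3), 1 / 3))

    def test_rows_sum_to_one_and_seeds_differ(self):
        T1 = em_init(20, 4, seed=1).T
        T2 = em_init(20, 4, seed=2).T
        assert T1.sum(axis=1) == pytest.approx(np.ones(20), abs=1e-12)
        assert not np.allclose(T1, T2)


def reference_bernoulli_mixture_em(D, K, T0, tol=1e-8, max_iter=2000):
    """Independent plain Bernoulli-mixture EM (no priors) for the chi->0
    comparison; deliberately written with explicit loops."""
    N, n = D.shape
    T = T0.copy()
    for _ in range(max_iter):
        tau = T.sum(0) / N
        theta = np.zeros((n, K))
        for k in range(K):
            theta[:, k] = (D * T[:, k : k + 1]).sum(0) / T[:, k].sum()
        theta = np.clip(theta, 1e-12, 1 - 1e-12)
        logw = np.log(tau)[None, :] + D @ np.log(theta) + (1 - D) @ np.log(1 - theta)
        logw -= logw.max(1, keepdims=True)
        T_new = np.exp(logw)
        T_new /= T_new.sum(1, keepdims=True)
        if np.abs(T_new - T).max() < tol:
            T = T_new
            break
        T = T_new
    return T, tau, theta


class TestEmFit:
    def test_k1_closed_form(self, rng):
        D = (rng.random((30, 5)) < 0.4).astype(int)
        model, resp = em_fit(D, 1, chi=1.0, seed=0)
        assert model.tau == pytest.approx([1.0])
        expect = (0.5 + D.sum(0)) / (1.0 + 30)
        assert model.theta[:, 0] == pytest.approx(expect)
        assert resp.T == pytest.approx(np.ones((30, 1)))

    def test_objective_monotone(self, rng):
        truth = bernoulli_mixture_truth()
        mm, _ = sample_mixture(truth, 300, seed=5)
        _, resp = em_fit(mm.D, 3, chi=1.0, seed=1)
        trace = np.array(resp.objective_trace)
        assert (np.diff(trace) >= -1e-8 * np.maximum(1.0, np.abs(trace[:-1]))).all()

    def test_recovers_planted_mixture(self):
        truth = bernoulli_mixture_truth()
        mm, labels = sample_mixture(truth, 900, seed=9)
        model, resp = best_of_restarts(mm.D, 3, chi=1.0, n_restarts=16, master_seed=3)
        assert ari(hard_assignment(resp.T), labels) >= 0.9

    def test_large_chi_shrinks_towards_prior(self, rng):
        truth = bernoulli_mixture_truth()
        mm, _ = sample_mixture(truth, 300, seed=2)
        m_small, _ = em_fit(mm.D, 2, chi=0.5, seed=0)
        m_large, _ = em_fit(mm.D, 2, chi=500.0, seed=0)
        assert np.abs(m_large.theta - 0.5).mean() < np.abs(m_small.theta - 0.5).mean()
        # at fixed responsibilities the weights shrink towards 1/K as chi grows
        T = rng.dirichlet(np.ones(2), size=100)
        assert np.abs(update_tau(T, 500.0) - 0.5).max() < np.abs(update_tau(T, 0.5) - 0.5).max()

    def test_chi_to_zero_matches_plain_bernoulli_mixture(self):
        truth = bernoulli_mixture_truth()
        mm, _ = sample_mixture(truth, 400, seed=7)
        T0 = em_init(400, 3, seed=4).T
        model, resp = em_fit(mm.D, 3, chi=1e-8, seed=0, init_T=T0, tol=1e-9)
        T_ref, tau_ref, theta_ref = reference_bernoulli_mixture_em(mm.D, 3, T0, tol=1e-9)
        assert resp.T == pytest.approx(T_ref, abs=1e-4)
        assert model.tau == pytest.approx(tau_ref, abs=1e-5)
        assert model.theta == pytest.approx(theta_ref, abs=1e-4)

    def test_label_switching_leaves_objective_unchanged(self, rng):
        truth = bernoulli_mixture_truth()
        mm, _ = sample_mixture(truth, 200, seed=3)
        model, resp = em_fit(mm.D, 3, chi=1.0, seed=1)
        perm = [2, 0, 1]
        permuted = MixtureModel(
            tau=model.tau[perm], chi=model.chi, theta=model.theta[:, perm]
        )
        assert permuted.data_loglik(mm.D) == pytest.approx(model.data_loglik(mm.D))


class TestRestartsAndSelection:
    def test_single_restart_equals_em_fit(self, rng):
        truth = bernoulli_mixture_truth()
        mm, _ = sample_mixture(truth, 200, seed=1)
        seed_seq = np.random.SeedSequence(5).spawn(1)[0]
        direct = em_fit(mm.D, 2, chi=1.0, seed=seed_seq)
        best = best_of_restarts(mm.D, 2, chi=1.0, n_restarts=1, master_seed=5)
        assert best[0].objective == pytest.approx(direct[0].objective)

    def test_best_objective_dominates_each_run(self, rng):
        truth = bernoulli_mixture_truth()
        mm, _ = sample_mixture(truth, 200, seed=1)
        best = best_of_restarts(mm.D, 3, chi=1.0, n_restarts=6, master_seed=9)
        for ss in np.random.SeedSequence(9).spawn(6):
            run = em_fit(mm.D, 3, chi=1.0, seed=ss)
            assert best[0].objective >= run[0].objective - 1e-9

    def test_aic_parameter_count(self, rng):
        D = (rng.random((50, 10)) < 0.3).astype(int)
        model, _ = em_fit(D, 3, chi=1.0, seed=0)
        # p = (K-1) + K*n = 2 + 30 = 32
        assert aic(model, D) == pytest.approx(-2 * model.data_loglik(D) + 2 * 32)

    def test_select_k_on_single_cluster_data(self, rng):
        D = (rng.random((300, 8)) < 0.3).astype(int)
        res = select_k(D, chi=1.0, k_range=range(1, 4), n_restarts=4, master_seed=0)
        assert res.k_best == 1

    def test_select_k_recovers_planted_k(self):
        truth = bernoulli_mixture_truth()
        mm, _ = sample_mixture(truth, 900, seed=21)
        res = select_k(mm.D, chi=1.0, k_range=range(1, 6), n_restarts=8, master_seed=2)
        assert res.k_best == 3

    def test_select_chi_prefers_stable_regime(self):
        truth = bernoulli_mixture_truth()
        mm, _ = sample_mixture(truth, 600, seed=33)
        res = select_chi(
            mm.D, chi_grid=(0.5, 1.0, 2.0), k_range=range(2, 5),
            n_restarts=6, master_seed=1,
        )
        assert res.chi_best in (0.5, 1.0, 2.0)
        assert max(res.mean_nmi.values()) == res.mean_nmi[res.chi_best]


class TestNmi:
    def test_identical_labellings(self):
        assert nmi([0, 0, 1, 1], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_label_permutation_invariance(self):
        a = [0, 0, 1, 1, 2, 2]
        b = [2, 2, 0, 0, 1, 1]
        assert nmi(a, b) == pytest.approx(1.0)
        assert nmi(a, b) == pytest.approx(nmi(b, a))

    def test_independent_labellings_near_zero(self, rng):
        a = rng.integers(0, 3, 5000)
        b = rng.integers(0, 3, 5000)
        assert nmi(a, b) < 0.01


class TestStructureEm:
    def test_empty_graph_data_keeps_empty_solution(self):
        """On data generated without interactions the structure loop keeps
        the frequency clustering (spurious edges penalty-suppressed)."""
        truth = bernoulli_mixture_truth()
        mm, labels = sample_mixture(truth, 900, seed=41)
        init = best_of_restarts(mm.D, 3, chi=1.0, n_restarts=8, master_seed=4)
        a_empty = ari(hard_assignment(init[1].T), labels)
        model, resp = em_with_structure(mm.D, 3, chi=1.0, seed=4, init=init)
        a_struct = ari(hard_assignment(resp.T), labels)
        assert a_struct >= a_empty - 0.05
        edges = [sum(len(g.parents[v]) for v in range(mm.n)) for c in model.graphs for g in c]
        assert max(edges) <= 6  # near-empty graphs

    def test_opposing_dependence_separated_only_with_structure(self):
        truth = opposing_dependence_truth()
        mm, labels = sample_mixture(truth, 600, seed=55)
        init = best_of_restarts(mm.D, 2, chi=1.0, n_restarts=8, master_seed=5)
        assert ari(hard_assignment(init[1].T), labels) <= 0.1
        model, resp = em_with_structure(mm.D, 2, chi=1.0, seed=5, init=init)
        assert ari(hard_assignment(resp.T), labels) >= 0.8

    def test_finalize_clusters_and_holdout_classification(self):
        truth = bernoulli_mixture_truth()
        mm, labels = sample_mixture(truth, 900, seed=61)
        model, resp = best_of_restarts(mm.D, 3, chi=1.0, n_restarts=8, master_seed=6)
        groups, final_T = finalize_clusters(mm.D, model, M=20, seed=6)
        assert all(gm.posterior.M == 20 for gm in groups)
        assert final_T.shape == (900, 3)
        # held-out samples classify to the cluster matching their true label
        held, held_labels = sample_mixture(truth, 300, seed=62)
        P = classify(held.D, groups, prior_over_groups=model.tau)
        assert ari(np.argmax(P, axis=1), held_labels) >= 0.9
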