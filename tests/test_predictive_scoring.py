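"""Posterior-predictive scoring, classification and the JSD/MDS map."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mutclust.bde_scoring import ScoringConfig
from mutclust.dag import Dag
from mutclust.predictive_scoring import (
    GroupModel,
    average_assignment,
    classify,
    dag_theta_tables,
    heterogeneity_map,
    js_divergence,
    loglik_profiles_given_dag,
    mc_loglik,
    pairwise_jsd,
    predictive_theta,
)
from mutclust.structure_search import PosteriorSample, enumerate_posterior, sample_posterior


class TestPredictiveTheta:
    def test_worked_example(self):
        # chi=1, no parents, 3 mutated and 1 unmutated training rows
        assert predictive_theta(np.array([3.0]), np.array([1.0]), 1.0, 0)[0] == pytest.approx(0.7)

    def test_unseen_configuration_falls_back_to_prior_mean(self):
        th = predictive_theta(np.zeros(2), np.zeros(2), 1.0, 1)
        assert th == pytest.approx([0.5, 0.5])

    def test_matches_direct_formula(self, rng):
        for m in (0, 1, 2):
            a1 = rng.integers(0, 20, size=2**m).astype(float)
            a0 = rng.integers(0, 20, size=2**m).astype(float)
            chi = 2.0
            a = chi / 2 ** (m + 1)
            expect = (a + a1) / (a + a1 + a + a0)
            assert predictive_theta(a1, a0, chi, m) == pytest.approx(expect)
            assert ((predictive_theta(a1, a0, chi, m) > 0) & (predictive_theta(a1, a0, chi, m) < 1)).all()


class TestProfileLoglik:
    def test_empty_graph_is_independent_bernoulli(self, small_matrix):
        dag = Dag.empty(3)
        th = dag_theta_tables(small_matrix.D, dag, chi=1.0)
        freqs = np.array([t[0] for t in th])
        profile = np.array([[1, 0, 1]])
        got = loglik_profiles_given_dag(profile, dag, th)[0]
        expect = np.log(freqs[0]) + np.log(1 - freqs[1]) + np.log(freqs[2])
        assert got == pytest.approx(expect)

    def test_all_zero_profile_under_empty_graph(self, small_matrix):
        dag = Dag.empty(3)
        th = dag_theta_tables(small_matrix.D, dag, chi=1.0)
        got = loglik_profiles_given_dag(np.zeros((1, 3), dtype=int), dag, th)[0]
        assert got == pytest.approx(sum(np.log(1 - t[0]) for t in th))

    def test_joint_distribution_sums_to_one(self, data4, plain_config):
        """The per-profile likelihood defines a proper distribution: summing
        over all 2^n binary vectors gives exactly 1 for any DAG."""
        dag = Dag.from_edges(4, [(0, 1), (2, 3)])
        th = dag_theta_tables(data4, dag, chi=1.0)
        profiles = np.array(list(itertools.product((0, 1), repeat=4)))
        total = np.exp(loglik_profiles_given_dag(profiles, dag, th)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_wrong_profile_length_rejected(self, data4):
        dag = Dag.empty(4)
        th = dag_theta_tables(data4, dag, chi=1.0)
        with pytest.raises(ValueError):
            loglik_profiles_given_dag(np.zeros((1, 3), dtype=int), dag, th)


class TestMcLoglik:
    def _group(self, D, dags, config=None):
        post = PosteriorSample(dags=dags, log_scores=[0.0] * len(dags))
        return GroupModel("g", post, D, config or ScoringConfig(prior_penalty=1.0))

    def test_m1_reduces_to_single_dag(self, data4):
        dag = Dag.from_edges(4, [(0, 1)])
        gm = self._group(data4, [dag])
        th = dag_theta_tables(data4, dag, chi=1.0)
        direct = loglik_profiles_given_dag(data4[:5], dag, th)
        assert mc_loglik(data4[:5], gm) == pytest.approx(direct)

    def test_repeated_identical_dags_change_nothing(self, data4):
        dag = Dag.from_edges(4, [(0, 1)])
        one = mc_loglik(data4[:5], self._group(data4, [dag]))
        five = mc_loglik(data4[:5], self._group(data4, [dag] * 5))
        assert five == pytest.approx(one)

    def test_approximates_exact_model_average(self, data4, plain_config):
        ep = enumerate_posterior(data4, plain_config)
        profiles = data4[:20]
        exact = np.zeros(len(profiles))
        for dag, lw in zip(ep.dags, ep.log_weights):
            th = dag_theta_tables(data4, dag, chi=1.0)
            exact += np.exp(lw) * np.exp(loglik_profiles_given_dag(profiles, dag, th))
        ps = sample_posterior(data4, plain_config, M=1000, seed=11)
        gm = GroupModel("g", ps, data4, plain_config)
        mc = np.exp(mc_loglik(profiles, gm))
        rel = np.abs(mc - exact) / exact
        assert rel.max() < 0.02

    def test_monotone_in_profile_fit(self, small_matrix):
        """Flipping a bit towards the training-data mode never lowers the
        empty-graph likelihood."""
        dag = Dag.empty(3)
        gm = self._group(small_matrix.D, [dag])
        freqs = small_matrix.D.mean(axis=0)
        profile = np.array([1 - (freqs > 0.5).astype(int)])  # anti-modal
        base = mc_loglik(profile, gm)[0]
        for j in range(3):
            flipped = profile.copy()
            flipped[0, j] = 1 - flipped[0, j]
            assert mc_loglik(flipped, gm)[0] >= base - 1e-12


class TestClassify:
    def _gm(self, D, label="g"):
        dag = Dag.empty(D.shape[1])
        post = PosteriorSample(dags=[dag], log_scores=[0.0])
        return GroupModel(label, post, D, ScoringConfig(prior_penalty=1.0))

    def test_single_group_gets_all_mass(self, data4):
        P = classify(data4[:5], [self._gm(data4)])
        assert P == pytest.approx(np.ones((5, 1)))

    def test_identical_groups_split_evenly(self, data4):
        P = classify(data4[:5], [self._gm(data4, "a"), self._gm(data4, "b")])
        assert P == pytest.approx(np.full((5, 2), 0.5), abs=1e-12)

    def test_rows_sum_to_one(self, data4, rng):
        D2 = (rng.random((30, 4)) < 0.7).astype(int)
        P = classify(data4[:10], [self._gm(data4), self._gm(D2)])
        assert P.sum(axis=1) == pytest.approx(np.ones(10), abs=1e-12)

    def test_planted_groups_classified_correctly(self, rng):
        """Two well-separated generating processes: nearly every sample is
        assigned to its own group."""
        n = 8
        Da = (rng.random((300, n)) < 0.15).astype(int)
        Db = (rng.random((300, n)) < 0.75).astype(int)
        gms = [self._gm(Da, "a"), self._gm(Db, "b")]
        Pa = classify(Da, gms)
        Pb = classify(Db, gms)
        acc = (np.argmax(Pa, 1) == 0).mean() * 0.5 + (np.argmax(Pb, 1) == 1).mean() * 0.5
        assert acc >= 0.95

    def test_average_assignment_range(self, data4):
        P = classify(data4[:5], [self._gm(data4, "a"), self._gm(data4, "b")])
        assert average_assignment(P) == pytest.approx(0.5, abs=1e-9)


class TestJsDivergence:
    def test_identical_vectors_give_zero(self):
        p = np.array([0.2, 0.3, 0.5])
        assert js_divergence(p, p) == 0.0

    def test_disjoint_vectors_give_ln2(self):
        assert js_divergence(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(np.log(2))

    def test_rejects_non_simplex(self):
        with pytest.raises(ValueError):
            js_divergence(np.array([0.5, 0.6]), np.array([0.5, 0.5]))

    @given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=6), st.integers(0, 10**6))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_properties_on_random_simplex_vectors(self, raw, seed):
        p = np.array(raw) / np.sum(raw)
        q_raw = np.random.default_rng(seed).random(len(raw)) + 0.01
        q = q_raw / q_raw.sum()
        d = js_divergence(p, q)
        assert 0.0 <= d <= np.log(2) + 1e-12
        assert d == pytest.approx(js_divergence(q, p), abs=1e-12)

    def test_matches_direct_definition(self, rng):
        for _ in range(10):
            p = rng.random(5) + 0.01
            p /= p.sum()
            q = rng.random(5) + 0.01
            q /= q.sum()
            m = (p + q) / 2
            expect = 0.5 * np.sum(p * np.log(p / m)) + 0.5 * np.sum(q * np.log(q / m))
            assert js_divergence(p, q) == pytest.approx(expect, abs=1e-12)

    def test_pairwise_matrix_consistent_with_scalar(self, rng):
        P = rng.random((6, 4)) + 0.05
        P /= P.sum(axis=1, keepdims=True)
        M = pairwise_jsd(P)
        for i in range(6):
            for j in range(6):
                assert M[i, j] == pytest.approx(js_divergence(P[i], P[j]), abs=1e-10)


class TestHeterogeneityMap:
    def test_needs_three_samples(self):
        with pytest.raises(ValueError):
            heterogeneity_map(np.array([[1.0, 0.0], [0.0, 1.0]]))

    def test_three_equidistant_points_form_equilateral_triangle(self):
        P = np.eye(3)
        coords = heterogeneity_map(P)
        d = [np.linalg.norm(coords[i] - coords[j]) for i, j in [(0, 1), (0, 2), (1, 2)]]
        assert d[0] == pytest.approx(d[1], rel=1e-6)
        assert d[0] == pytest.approx(d[2], rel=1e-6)

    def test_duplicated_samples_coincide(self):
        P = np.array([[0.9, 0.1], [0.9, 0.1], [0.2, 0.8], [0.5, 0.5]])
        coords = heterogeneity_map(P)
        assert coords[0] == pytest.approx(coords[1], abs=1e-8)

    def test_embedding_correlates_with_jsd(self, rng):
        """On four well-separated groups the 2D distances track the input
        divergences (Spearman >= 0.7)."""
        from scipy.stats import spearmanr

        centers = np.array(
            [[0.85, 0.05, 0.05, 0.05], [0.05, 0.85, 0.05, 0.05],
             [0.05, 0.05, 0.85, 0.05], [0.05, 0.05, 0.05, 0.85]]
        )
        P = np.vstack([c + rng.uniform(-0.03, 0.03, size=(20, 4)) for c in centers])
        P = np.clip(P, 1e-6, None)
        P /= P.sum(axis=1, keepdims=True)
        coords = heterogeneity_map(P)
        D_in = pairwise_jsd(P)
        iu = np.triu_indices(len(P), 1)
        D_out = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        rho = spearmanr(D_in[iu], D_out[iu]).statistic
        assert rho >= 0.7

    def test_matches_reference_pcoa(self, rng):
        """Cross-check the Torgerson embedding against scikit-bio's PCoA on
        the same distance matrix (up to per-axis sign)."""
        from skbio.stats.ordination import pcoa
        from skbio import DistanceMatrix

        P = rng.random((10, 3)) + 0.05
        P /= P.sum(axis=1, keepdims=True)
        Dm = pairwise_jsd(P)
        ours = heterogeneity_map(P)
        ref = pcoa(DistanceMatrix(Dm), number_of_dimensions=2).samples.to_numpy()
        for axis in range(2):
            r = ref[:, axis]
            o = ours[:, axis]
            assert min(np.abs(o - r).max(), np.abs(o + r).max()) < 1e-6
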