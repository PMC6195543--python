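"""Mixture-of-Bayesian-networks clustering of binary mutation profiles.

Each sample ``D_i`` is generated by one of ``K`` latent components, each a
Bayesian network ``(G_k, theta_k)`` with mixture weight ``tau_k``.  Fitting
proceeds in two phases:

1. *Frequency phase* — all graphs empty, so each component is a product of
   Bernoullis; an EM algorithm finds MAP estimates under a Dirichlet(chi)
   prior on ``tau`` and Beta(chi/2, chi/2) priors on each ``theta_jk``.  The
   update equations are posterior means,

       tau_k   = (chi   + sum_i T_ik)        / (chi K + N)
       theta_jk = (chi/2 + sum_i D_ij T_ik)  / (chi   + sum_i T_ik)

   which coincide with the M-step maximisers of the pseudocount-shifted
   log-posterior recorded as the objective, so the objective is provably
   non-decreasing (a violation raises, as a bug trap).  With chi -> 0 the
   procedure reduces to a plain Bernoulli mixture model.

2. *Structure phase* — an alternating loop: given responsibilities, learn a
   MAP DAG per cluster from responsibility-weighted BDe scores; given the
   graphs, run the inner EM (posterior-predictive thetas per parent
   configuration, then responsibilities) to convergence.  Because graph
   space is discrete the outer loop can cycle; cycles are detected on the
   hard assignment vector and broken by letting each cluster carry the small
   collection of graphs visited in the cycle, averaging their likelihoods.

Model selection scans K (lowest AIC, ties to smaller K) within a grid of
chi values, and picks the chi whose labelling agrees best (mean pairwise
NMI) with the labellings across the rest of the grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .bde_scoring import ScoringConfig
from .dag import Dag
from .predictive_scoring import (
    GroupModel,
    classify,
    dag_theta_tables,
    loglik_profiles_given_dag,
)
from .structure_search import (
    complete_skeleton,
    initial_skeleton,
    map_dag,
    sample_posterior,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MixtureModel",
    "Responsibilities",
    "em_init",
    "update_tau",
    "update_theta",
    "loglik_empty",
    "update_responsibilities",
    "em_fit",
    "best_of_restarts",
    "aic",
    "select_k",
    "select_chi",
    "nmi",
    "ari",
    "hard_assignment",
    "em_with_structure",
    "finalize_clusters",
]


@dataclass
class MixtureModel:
    """Fitted mixture: weights, per-cluster parameters, optional graphs."""

    tau: np.ndarray
    chi: float
    theta: np.ndarray | None = None  # (n, K) in the empty-graph phase
    graphs: list[list[Dag]] | None = None  # per-cluster graph collection
    theta_tables: list[list[list[np.ndarray]]] | None = None
    loglik: float = float("nan")
    objective: float = float("nan")
    responsibilities: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, float)
        if abs(self.tau.sum() - 1.0) > 1e-8 or (self.tau <= 0).any():
            raise ValueError("tau must be a positive vector summing to 1")
        if self.theta is not None:
            self.theta = np.asarray(self.theta, float)
            if ((self.theta <= 0) | (self.theta >= 1)).any():
                raise ValueError("theta must lie strictly inside (0, 1)")

    @property
    def K(self) -> int:
        return len(self.tau)

    @property
    def n(self) -> int:
        if self.theta is not None:
            return self.theta.shape[0]
        return self.graphs[0][0].n

    def per_sample_logliks(self, D: np.ndarray) -> np.ndarray:
        """(N, K) matrix of ln P(D_i | component k)."""
        if self.graphs is None:
            return loglik_empty(D, self.theta)
        cols = []
        for k in range(self.K):
            per_graph = np.stack(
                [
                    loglik_profiles_given_dag(D, g, th)
                    for g, th in zip(self.graphs[k], self.theta_tables[k])
                ]
            )
            cols.append(logsumexp(per_graph, axis=0) - np.log(len(self.graphs[k])))
        return np.column_stack(cols)

    def data_loglik(self, D: np.ndarray) -> float:
        L = self.per_sample_logliks(D) + np.log(self.tau)
        return float(logsumexp(L, axis=1).sum())


@dataclass
class Responsibilities:
    """Soft cluster memberships T_ik with the fit trace."""

    T: np.ndarray
    n_iter: int = 0
    objective_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, float)
        if (self.T < 0).any() or np.abs(self.T.sum(axis=1) - 1.0).max() > 1e-8:
            raise ValueError("responsibility rows must lie on the simplex")


def em_init(N: int, K: int, seed=0, epsilon: float = 0.01) -> Responsibilities:
    """Near-uniform start: T_ik = (1/K)(1 + eps_ik), renormalised, with
    eps_ik uniform on (-epsilon, epsilon).  The exactly uniform state is an
    unstable fixed point, hence the perturbation."""
    rng = np.random.default_rng(seed)
    T = (1.0 / K) * (1.0 + rng.uniform(-epsilon, epsilon, size=(N, K)))
    T /= T.sum(axis=1, keepdims=True)
    return Responsibilities(T)


def update_tau(T: np.ndarray, chi: float) -> np.ndarray:
    """Cluster weights: (chi + sum_i T_ik) / (chi K + N)."""
    T = np.asarray(T, float)
    N, K = T.shape
    return (chi + T.sum(axis=0)) / (chi * K + N)


def update_theta(D: np.ndarray, T: np.ndarray, chi: float) -> np.ndarray:
    """Per-gene, per-cluster mutation probabilities, shape (n, K):
    (chi/2 + sum_i D_ij T_ik) / (chi + sum_i T_ik)."""
    T = np.asarray(T, float)
    num = chi / 2.0 + D.T.astype(float) @ T
    den = chi + T.sum(axis=0)
    return num / den


def loglik_empty(D: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """(N, K) log-likelihoods under empty graphs: independent Bernoullis
    with per-cluster frequencies theta (n, K)."""
    theta = np.atleast_2d(np.asarray(theta, float))
    if theta.ndim == 1:
        theta = theta[:, None]
    Df = D.astype(float)
    return Df @ np.log(theta) + (1.0 - Df) @ np.log1p(-theta)


def update_responsibilities(logliks: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """Row-wise softmax of ln tau_k + ln P(D_i | k); log-sum-exp stable."""
    L = np.asarray(logliks, float) + np.log(np.asarray(tau, float))
    L = L - L.max(axis=1, keepdims=True)
    T = np.exp(L)
    return T / T.sum(axis=1, keepdims=True)


def _map_objective(
    D: np.ndarray, tau: np.ndarray, theta: np.ndarray, chi: float
) -> tuple[float, np.ndarray]:
    """Penalised log-posterior (up to additive constants) whose M-step
    maximisers are exactly the posterior-mean updates above, plus the
    per-sample loglik matrix as a by-product."""
    L = loglik_empty(D, theta)
    ll = float(logsumexp(L + np.log(tau), axis=1).sum())
    prior = chi * np.log(tau).sum() + (chi / 2.0) * (
        np.log(theta).sum() + np.log1p(-theta).sum()
    )
    return ll + prior, L


def em_fit(
    D: np.ndarray,
    K: int,
    chi: float = 1.0,
    seed=0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    epsilon: float = 0.01,
    init_T: np.ndarray | None = None,
) -> tuple[MixtureModel, Responsibilities]:
    """EM MAP fit of the empty-graph (frequency-only) mixture.

    Alternates the weight/parameter updates and the responsibility update
    until the maximum absolute change in T falls below ``tol`` or
    ``max_iter`` is reached.  The recorded objective must never decrease;
    a decrease beyond numerical slack raises RuntimeError.
    """
    N = D.shape[0]
    T = em_init(N, K, seed, epsilon).T if init_T is None else np.asarray(init_T, float)
    trace: list[float] = []
    ll_final = np.nan
    for it in range(1, max_iter + 1):
        tau = update_tau(T, chi)
        theta = update_theta(D, T, chi)
        obj, L = _map_objective(D, tau, theta, chi)
        if trace and obj < trace[-1] - 1e-8 * max(1.0, abs(trace[-1])):
            raise RuntimeError(
                f"EM objective decreased at iteration {it}: {trace[-1]} -> {obj}"
            )
        trace.append(obj)
        T_new = update_responsibilities(L, tau)
        delta = np.abs(T_new - T).max()
        T = T_new
        if delta < tol:
            break
    tau = update_tau(T, chi)
    theta = update_theta(D, T, chi)
    _, L = _map_objective(D, tau, theta, chi)
    ll_final = float(logsumexp(L + np.log(tau), axis=1).sum())
    model = MixtureModel(
        tau=tau,
        chi=chi,
        theta=theta,
        loglik=ll_final,
        objective=trace[-1],
        responsibilities=T,
    )
    return model, Responsibilities(T, n_iter=it, objective_trace=trace)


def _restart_seeds(master_seed, n: int) -> list[np.random.SeedSequence]:
    """Deterministic per-restart seeds spawned from a master seed."""
    if isinstance(master_seed, np.random.SeedSequence):
        return master_seed.spawn(n)
    return np.random.SeedSequence(master_seed).spawn(n)


def best_of_restarts(
    D: np.ndarray,
    K: int,
    chi: float = 1.0,
    n_restarts: int = 240,
    master_seed=0,
    **em_kwargs,
) -> tuple[MixtureModel, Responsibilities]:
    """Run ``em_fit`` from ``n_restarts`` random perturbations (seeds spawned
    deterministically from ``master_seed``) and keep the highest objective."""
    best: tuple[MixtureModel, Responsibilities] | None = None
    for ss in _restart_seeds(master_seed, n_restarts):
        fit = em_fit(D, K, chi, seed=ss, **em_kwargs)
        if best is None or fit[0].objective > best[0].objective:
            best = fit
    return best


def _n_params(model: MixtureModel) -> int:
    K, n = model.K, model.n
    p = K - 1
    if model.graphs is None:
        p += K * n
    else:
        for k in range(K):
            g = model.graphs[k][0]  # collections only arise transiently
            p += sum(2 ** len(ps) for ps in g.parents)
    return p


def aic(model: MixtureModel, D: np.ndarray) -> float:
    """Akaike information criterion: -2 max log-likelihood + 2 p with
    p = (K - 1) + K n free parameters for empty graphs (2**m per node with
    m parents otherwise).  The penalty form is pluggable via this function.
    """
    return -2.0 * model.data_loglik(D) + 2.0 * _n_params(model)


def hard_assignment(T: np.ndarray) -> np.ndarray:
    """argmax_k T_ik, ties to the lowest cluster index."""
    return np.argmax(T, axis=1)


def nmi(labels_a: Sequence[int], labels_b: Sequence[int]) -> float:
    """Normalised mutual information, arithmetic-mean normalisation;
    symmetric and invariant to label permutations."""
    return float(
        normalized_mutual_info_score(labels_a, labels_b, average_method="arithmetic")
    )


def ari(labels_a: Sequence[int], labels_b: Sequence[int]) -> float:
    """Adjusted Rand index between two labellings."""
    return float(adjusted_rand_score(labels_a, labels_b))


@dataclass
class SelectKResult:
    k_best: int
    aics: dict[int, float]
    fits: dict[int, tuple[MixtureModel, Responsibilities]]

    @property
    def best_fit(self) -> tuple[MixtureModel, Responsibilities]:
        return self.fits[self.k_best]


def select_k(
    D: np.ndarray,
    chi: float = 1.0,
    k_range: Sequence[int] = range(1, 7),
    n_restarts: int = 24,
    master_seed=0,
    **em_kwargs,
) -> SelectKResult:
    """Choose the number of clusters by lowest AIC over ``k_range``;
    ties break towards the smaller K (parsimony)."""
    aics: dict[int, float] = {}
    fits = {}
    for K in k_range:
        fit = best_of_restarts(
            D, K, chi, n_restarts=n_restarts, master_seed=master_seed, **em_kwargs
        )
        fits[K] = fit
        aics[K] = aic(fit[0], D)
    k_best = min(sorted(aics), key=lambda k: (aics[k], k))
    return SelectKResult(k_best, aics, fits)


@dataclass
class SelectChiResult:
    chi_best: float
    k_by_chi: dict[float, int]
    labels_by_chi: dict[float, np.ndarray]
    mean_nmi: dict[float, float]


DEFAULT_CHI_GRID = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0)


def select_chi(
    D: np.ndarray,
    chi_grid: Sequence[float] = DEFAULT_CHI_GRID,
    k_range: Sequence[int] = range(1, 7),
    n_restarts: int = 24,
    master_seed=0,
    **em_kwargs,
) -> SelectChiResult:
    """Pick the pseudocount chi whose clustering (at its own AIC-selected K)
    has the highest mean NMI with the clusterings across the rest of the
    grid; ties go to the smallest chi (stability criterion)."""
    labels: dict[float, np.ndarray] = {}
    ks: dict[float, int] = {}
    for c in chi_grid:
        res = select_k(
            D, c, k_range, n_restarts=n_restarts, master_seed=master_seed, **em_kwargs
        )
        ks[c] = res.k_best
        labels[c] = hard_assignment(res.best_fit[1].T)
    mean_nmi = {}
    for c in chi_grid:
        others = [nmi(labels[c], labels[o]) for o in chi_grid if o != c]
        mean_nmi[c] = float(np.mean(others)) if others else 1.0
    chi_best = min(sorted(chi_grid), key=lambda c: (-mean_nmi[c], c))
    return SelectChiResult(chi_best, ks, labels, mean_nmi)


# ---------------------------------------------------------------------------
# structure-aware clustering


def _structured_logliks(
    D: np.ndarray,
    collections: list[list[Dag]],
    T: np.ndarray,
    chi: float,
) -> tuple[np.ndarray, list[list[list[np.ndarray]]]]:
    """Per-cluster likelihoods under the current graph collections, with
    thetas re-estimated from responsibility-weighted counts."""
    K = len(collections)
    tables: list[list[list[np.ndarray]]] = []
    cols = []
    for k in range(K):
        per_graph = []
        ktabs = []
        for g in collections[k]:
            th = dag_theta_tables(D, g, chi, weights=T[:, k])
            ktabs.append(th)
            per_graph.append(loglik_profiles_given_dag(D, g, th))
        tables.append(ktabs)
        cols.append(logsumexp(np.stack(per_graph), axis=0) - np.log(len(per_graph)))
    return np.column_stack(cols), tables


def co_mutation_features(D: np.ndarray, pairs=None) -> np.ndarray:
    """Pairwise agreement indicators 1{D_a == D_b}, appended to the genes.

    The frequency of an agreement column is the degree of co-occurrence vs
    mutual exclusivity of the pair, so a frequency-only EM on the augmented
    matrix can separate clusters that differ only in their interactions —
    the regime where the plain empty-graph EM sits at an uninformative
    saddle.  Used purely to initialise the structure loop.
    """
    n = D.shape[1]
    if pairs is None:
        pairs = [(a, b) for a in range(n) for b in range(a + 1, n)]
    cols = [(D[:, a] == D[:, b]).astype(np.int8) for a, b in pairs]
    return np.column_stack([D] + cols) if cols else D


def _structure_loop(
    D: np.ndarray,
    T: np.ndarray,
    chi: float,
    config: ScoringConfig,
    skeleton: dict[int, set[int]],
    map_seeds: list[np.random.SeedSequence],
    outer_max: int,
    tol: float,
    inner_max: int,
    map_restarts: int,
    empty_threshold: float,
) -> tuple[MixtureModel, Responsibilities]:
    """One run of the alternating loop from a given responsibility matrix."""
    K = T.shape[1]
    n = D.shape[1]
    tau = update_tau(T, chi)
    history: list[tuple[int, ...]] = []
    graph_history: list[list[Dag]] = []
    collections: list[list[Dag]] = [[Dag.empty(n)] for _ in range(K)]
    trace: list[float] = []

    def inner_em(T, tau, collections):
        for _ in range(inner_max):
            L, tables = _structured_logliks(D, collections, T, chi)
            T_new = update_responsibilities(L, tau)
            tau = update_tau(T_new, chi)
            delta = np.abs(T_new - T).max()
            T = T_new
            if delta < tol:
                break
        L, tables = _structured_logliks(D, collections, T, chi)
        ll = float(logsumexp(L + np.log(tau), axis=1).sum())
        return T, tau, tables, L, ll

    outer = 0
    ll = -np.inf
    tables: list[list[list[np.ndarray]]] = []
    while outer < outer_max:
        graphs = [
            map_dag(
                D,
                config,
                skeleton=skeleton,
                restarts=map_restarts,
                seed=map_seeds[outer % len(map_seeds)],
                weights=T[:, k],
            )
            for k in range(K)
        ]
        collections = [[g] for g in graphs]
        T, tau, tables, L, ll = inner_em(T, tau, collections)
        trace.append(ll)

        # drop clusters that lost all their mass
        mass = T.sum(axis=0)
        if (mass < empty_threshold).any() and K > 1:
            keep = mass >= empty_threshold
            dropped = int((~keep).sum())
            logger.warning("dropping %d empty cluster(s); K -> %d", dropped, K - dropped)
            T = T[:, keep]
            T /= T.sum(axis=1, keepdims=True)
            K = T.shape[1]
            tau = update_tau(T, chi)
            history.clear()
            graph_history.clear()
            outer += 1
            continue

        hard = tuple(hard_assignment(T))
        if history and hard == history[-1]:
            break
        if hard in history:
            # periodic orbit: pool the graphs seen over the cycle
            start = history.index(hard)
            cycle_graphs = graph_history[start:] + [graphs]
            collections = [
                sorted({step[k] for step in cycle_graphs}, key=lambda g: g.parents)
                for k in range(K)
            ]
            T, tau, tables, L, ll = inner_em(T, tau, collections)
            trace.append(ll)
            break
        history.append(hard)
        graph_history.append(graphs)
        outer += 1

    model = MixtureModel(
        tau=tau,
        chi=chi,
        theta=None,
        graphs=collections,
        theta_tables=tables,
        loglik=ll,
        objective=ll,
        responsibilities=T,
    )
    return model, Responsibilities(T, n_iter=outer, objective_trace=trace)


def em_with_structure(
    D: np.ndarray,
    K: int,
    chi: float = 1.0,
    config: ScoringConfig | None = None,
    seed=0,
    outer_max: int = 20,
    tol: float = 1e-6,
    inner_max: int = 500,
    skeleton: dict[int, set[int]] | None = None,
    map_restarts: int = 3,
    empty_threshold: float = 1.0,
    init: tuple[MixtureModel, Responsibilities] | None = None,
    n_init_restarts: int = 8,
    n_interaction_inits: int = 2,
) -> tuple[MixtureModel, Responsibilities]:
    """Alternating structure-aware clustering.

    Starts from a converged empty-graph fit, then repeats: (1) learn a MAP
    DAG per cluster from responsibility-weighted scores; (2) run the inner
    EM (weighted predictive thetas, then responsibilities) to convergence.
    A run terminates when the hard assignment repeats; a periodic orbit is
    broken by pooling the graphs visited in the cycle into per-cluster
    collections whose likelihoods are averaged.  Clusters whose total
    responsibility falls below ``empty_threshold`` (one sample-equivalent)
    are dropped.

    When clusters share all marginal frequencies the empty-graph fit is an
    uninformative saddle and the responsibility-weighted scores cannot see
    the interaction edges, so in addition to the empty-graph start the loop
    is restarted ``n_interaction_inits`` times from frequency-EM fits on
    the co-mutation-augmented matrix (:func:`co_mutation_features`); the
    run with the lowest final AIC wins (richer graphs must buy their extra
    parameters, which bare likelihood comparison would not enforce).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    init_ss, aug_ss, *map_ss = ss.spawn(outer_max + 2)
    if init is None:
        init = best_of_restarts(
            D, K, chi, n_restarts=n_init_restarts, master_seed=init_ss, tol=tol
        )
    n = D.shape[1]
    if config is None:
        config = ScoringConfig(chi=chi, prior_penalty=1.0, global_penalty=2.0)
    if skeleton is None:
        skeleton = complete_skeleton(n) if n <= 25 else initial_skeleton(D)

    starts: list[np.ndarray] = [init[1].T.copy()]
    if n_interaction_inits > 0:
        pairs = [(a, b) for a in range(n) for b in skeleton[a] if a < b]
        D_aug = co_mutation_features(D, pairs)
        for ss_r in aug_ss.spawn(n_interaction_inits):
            _, resp_aug = best_of_restarts(
                D_aug, K, chi, n_restarts=4, master_seed=ss_r, tol=tol
            )
            starts.append(resp_aug.T.copy())

    best: tuple[MixtureModel, Responsibilities] | None = None
    best_aic = np.inf
    for T0 in starts:
        run = _structure_loop(
            D, T0, chi, config, skeleton, map_ss, outer_max, tol,
            inner_max, map_restarts, empty_threshold,
        )
        run_aic = aic(run[0], D)
        if best is None or run_aic < best_aic:
            best, best_aic = run, run_aic
    return best


def finalize_clusters(
    D: np.ndarray,
    model: MixtureModel,
    M: int = 100,
    seed=0,
    config: ScoringConfig | None = None,
    skeleton: dict[int, set[int]] | None = None,
) -> tuple[list[GroupModel], np.ndarray]:
    """Draw ``M`` posterior DAGs per cluster (responsibility-weighted data)
    and return the cluster GroupModels plus final membership probabilities
    of the training samples under those models."""
    if model.responsibilities is None:
        raise ValueError("model carries no responsibilities; fit it first")
    T = model.responsibilities
    K = model.K
    if config is None:
        config = ScoringConfig(chi=model.chi, prior_penalty=1.0, global_penalty=2.0)
    n = D.shape[1]
    if skeleton is None:
        skeleton = complete_skeleton(n) if n <= 15 else initial_skeleton(D)
    seeds = np.random.SeedSequence(seed).spawn(K)
    group_models = []
    for k in range(K):
        post = sample_posterior(
            D,
            config,
            skeleton=skeleton,
            M=M,
            seed=seeds[k],
            weights=T[:, k],
        )
        group_models.append(
            GroupModel(
                label=f"cluster_{k}",
                posterior=post,
                D_train=D,
                config=config,
                weights=T[:, k],
            )
        )
    final_T = classify(D, group_models, prior_over_groups=model.tau)
    return group_models, final_T
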