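"""Posterior-predictive scoring of mutation profiles against group models.

Each group (cancer type or cluster) is summarised by a sample of M DAGs from
its structure posterior together with the training data the predictive
distribution conditions on.  A profile's fit to one DAG multiplies, over
nodes, the posterior-mean Bernoulli probability

    P(X = 1 | G, Y) = (alpha + a1_Y) / (alpha + a1_Y + beta + a0_Y)

given the parent configuration Y read off the profile; the group likelihood
is the Monte Carlo average over the M DAGs.  Normalising the per-group
likelihoods (times a group prior) yields membership probability vectors,
whose pairwise Jensen-Shannon divergences drive the 2D heterogeneity map
via classical (Torgerson) multidimensional scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp, rel_entr

from .bde_scoring import ScoringConfig, config_counts, parent_config_index
from .dag import Dag
from .structure_search import PosteriorSample

__all__ = [
    "GroupModel",
    "predictive_theta",
    "dag_theta_tables",
    "loglik_profile_given_dag",
    "loglik_profiles_given_dag",
    "mc_loglik",
    "classify",
    "average_assignment",
    "js_divergence",
    "pairwise_jsd",
    "heterogeneity_map",
]


def predictive_theta(
    a1: np.ndarray, a0: np.ndarray, chi: float, m: int
) -> np.ndarray:
    """Posterior-mean mutation probability per parent configuration.

    ``a1``/``a0`` are (possibly fractional) counts of X=1 / X=0 under each
    of the 2**m configurations; ``alpha = beta = chi / 2**(m+1)``.  Always
    strictly inside (0, 1); with no training rows for a configuration the
    value falls back to the prior mean 1/2.
    """
    a = chi / 2 ** (m + 1)
    return (a + np.asarray(a1, float)) / (2 * a + np.asarray(a1, float) + np.asarray(a0, float))


def dag_theta_tables(
    D_train: np.ndarray,
    dag: Dag,
    chi: float,
    weights: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Per-node predictive theta tables (length 2**m each) for one DAG."""
    tables = []
    for v, ps in enumerate(dag.parents):
        a1, a0 = config_counts(D_train, v, ps, weights)
        tables.append(predictive_theta(a1, a0, chi, len(ps)))
    return tables


@dataclass
class GroupModel:
    """Posterior-predictive model of one group of samples."""

    label: str
    posterior: PosteriorSample
    D_train: np.ndarray
    config: ScoringConfig = field(default_factory=ScoringConfig)
    weights: np.ndarray | None = None  # responsibilities for cluster models
    _thetas: list[list[np.ndarray]] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.D_train.shape[1] != self.posterior.n:
            raise ValueError("training matrix and posterior DAGs disagree on n")

    @property
    def n(self) -> int:
        return self.posterior.n

    def theta_tables(self) -> list[list[np.ndarray]]:
        if self._thetas is None:
            self._thetas = [
                dag_theta_tables(self.D_train, dag, self.config.chi, self.weights)
                for dag in self.posterior.dags
            ]
        return self._thetas


def loglik_profiles_given_dag(
    profiles: np.ndarray, dag: Dag, thetas: list[np.ndarray]
) -> np.ndarray:
    """Log-likelihood of each profile (rows) under one DAG with given theta
    tables; vectorised over profiles."""
    profiles = np.atleast_2d(profiles)
    if profiles.shape[1] != dag.n:
        raise ValueError(
            f"profile length {profiles.shape[1]} does not match n={dag.n}"
        )
    ll = np.zeros(profiles.shape[0])
    for v, ps in enumerate(dag.parents):
        idx = parent_config_index(profiles, ps)
        th = thetas[v][idx]
        x = profiles[:, v]
        ll += np.where(x == 1, np.log(th), np.log1p(-th))
    return ll


def loglik_profile_given_dag(
    profile: np.ndarray, dag: Dag, group_model: GroupModel, dag_index: int = 0
) -> float:
    """Log P(profile | G_j) for the j-th DAG of a group model."""
    thetas = group_model.theta_tables()[dag_index]
    return float(
        loglik_profiles_given_dag(np.atleast_2d(profile), group_model.posterior.dags[dag_index], thetas)[0]
    )


def mc_loglik(profiles: np.ndarray, group_model: GroupModel) -> np.ndarray:
    """Monte Carlo model-averaged log-likelihood, ln[(1/M) sum_j P(D_i|G_j)],
    computed with log-sum-exp for stability."""
    profiles = np.atleast_2d(profiles)
    M = group_model.posterior.M
    per_dag = np.stack(
        [
            loglik_profiles_given_dag(profiles, dag, th)
            for dag, th in zip(group_model.posterior.dags, group_model.theta_tables())
        ]
    )  # (M, N)
    return logsumexp(per_dag, axis=0) - np.log(M)


def classify(
    profiles: np.ndarray,
    group_models: list[GroupModel],
    prior_over_groups: np.ndarray | None = None,
) -> np.ndarray:
    """Per-sample membership probabilities over groups.

    ``P(k | D_i)`` proportional to ``P(D_i | k) P(k)``; a uniform prior by
    default.  Rows sum to 1; the result is invariant to adding a constant to
    all log-likelihoods of a sample.
    """
    K = len(group_models)
    if K < 1:
        raise ValueError("need at least one group model")
    if prior_over_groups is None:
        log_prior = np.zeros(K)
    else:
        prior = np.asarray(prior_over_groups, float)
        if prior.shape != (K,) or (prior <= 0).any():
            raise ValueError("prior must be a positive vector of length K")
        log_prior = np.log(prior / prior.sum())
    L = np.column_stack([mc_loglik(profiles, gm) for gm in group_models])
    L = L + log_prior
    L -= L.max(axis=1, keepdims=True)
    P = np.exp(L)
    P /= P.sum(axis=1, keepdims=True)
    return P


def average_assignment(classification: np.ndarray) -> float:
    """Mean over samples of the top membership probability, max_k P(k|D_i):
    how concentrated the group assignments are (1 = fully confident)."""
    return float(np.max(classification, axis=1).mean())


def _check_simplex(p: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    p = np.asarray(p, float)
    if (p < -tol).any() or abs(p.sum() - 1.0) > tol:
        raise ValueError("input is not a probability vector")
    return np.clip(p, 0.0, None)


def js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence in nats: symmetric, zero iff p == q,
    bounded by ln 2."""
    p, q = _check_simplex(p), _check_simplex(q)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    m = 0.5 * (p + q)
    return float(0.5 * rel_entr(p, m).sum() + 0.5 * rel_entr(q, m).sum())


def pairwise_jsd(P: np.ndarray) -> np.ndarray:
    """All-pairs JSD matrix for row-stochastic P, via JSD(p,q) = H(m) -
    (H(p) + H(q)) / 2."""
    P = np.asarray(P, float)
    H = -np.sum(np.where(P > 0, P * np.log(np.where(P > 0, P, 1.0)), 0.0), axis=1)
    N = P.shape[0]
    out = np.zeros((N, N))
    for i in range(N):
        Mmid = 0.5 * (P[i][None, :] + P[i:])
        Hm = -np.sum(
            np.where(Mmid > 0, Mmid * np.log(np.where(Mmid > 0, Mmid, 1.0)), 0.0),
            axis=1,
        )
        d = Hm - 0.5 * (H[i] + H[i:])
        out[i, i:] = out[i:, i] = np.clip(d, 0.0, None)
    return out


def heterogeneity_map(classification: np.ndarray) -> np.ndarray:
    """2D sample map: classical (Torgerson) MDS of the pairwise JSD matrix.

    Returns (N, 2) coordinates, deterministic up to rigid motion; the sign
    of each axis is fixed so its largest-magnitude coordinate is positive.
    """
    P = np.atleast_2d(classification)
    N = P.shape[0]
    if N < 3:
        raise ValueError("need at least 3 samples for a 2D map")
    Dm = pairwise_jsd(P)
    J = np.eye(N) - np.ones((N, N)) / N
    B = -0.5 * J @ (Dm**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:2]
    coords = vecs[:, order] * np.sqrt(np.clip(vals[order], 0.0, None))
    for a in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, a]))
        if coords[i, a] < 0:
            coords[:, a] = -coords[:, a]
    return coords
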