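"""Synthetic data with planted ground truth.

Generates everything the pipeline consumes — DAG-mixture mutation matrices,
imperfect prior networks and clinical tables with cluster-specific survival
effects — so that structure recovery, clustering and survival evaluation
can all be tested against a known truth without any external download.

Default scales follow the desk-scale study conditions used throughout the
test suite: a three-component Bernoulli mixture with 900 samples over 20
genes and cluster-specific signature genes separated by 0.5 in mutation
probability, and the named opposing-dependence fixture in which two
clusters share every marginal frequency (0.5 everywhere) and differ only in
the direction of the pairwise dependence — the scenario that frequency-only
clustering cannot separate in principle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bde_scoring import parent_config_index
from .dag import Dag
from .data_io import ClinicalTable, MutationMatrix, PriorNetwork, STAGE_LEVELS

__all__ = [
    "GroundTruth",
    "random_dag",
    "random_theta",
    "sample_profiles",
    "sample_mixture",
    "corrupt_prior",
    "sample_clinical",
    "bernoulli_mixture_truth",
    "opposing_dependence_truth",
    "strong_signal_dag_truth",
]


@dataclass
class GroundTruth:
    """Planted mixture of Bayesian networks plus survival effect sizes."""

    dags: list[Dag]
    thetas: list[list[np.ndarray]]  # per cluster, per node, length 2**m
    tau: np.ndarray
    gene_names: list[str] = field(default_factory=list)
    log_hr: np.ndarray | None = None  # per-cluster log hazard ratio

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, float)
        if abs(self.tau.sum() - 1.0) > 1e-8 or (self.tau <= 0).any():
            raise ValueError("tau must be positive and sum to 1")
        if len(self.dags) != len(self.tau) or len(self.thetas) != len(self.tau):
            raise ValueError("inconsistent number of clusters")
        for dag, th in zip(self.dags, self.thetas):
            for v, ps in enumerate(dag.parents):
                t = np.asarray(th[v], float)
                if t.shape != (2 ** len(ps),):
                    raise ValueError(f"theta table for node {v} has wrong length")
                if ((t <= 0) | (t >= 1)).any():
                    raise ValueError("theta must lie strictly inside (0, 1)")
        if not self.gene_names:
            self.gene_names = [f"G{j:03d}" for j in range(self.n)]

    @property
    def K(self) -> int:
        return len(self.tau)

    @property
    def n(self) -> int:
        return self.dags[0].n

    def true_edges(self) -> set[frozenset[int]]:
        return {e for dag in self.dags for e in dag.skeleton_pairs()}


def random_dag(n: int, max_parents: int = 3, edge_prob: float = 0.2, seed=0) -> Dag:
    """Random DAG: edges only from lower to higher rank in a random node
    order (acyclic by construction), density set by ``edge_prob``, parent
    sets capped at ``max_parents``."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    parents: list[list[int]] = [[] for _ in range(n)]
    for j in range(1, n):
        v = int(order[j])
        for i in range(j):
            u = int(order[i])
            if len(parents[v]) >= max_parents:
                break
            if rng.random() < edge_prob:
                parents[v].append(u)
    return Dag(n, tuple(tuple(sorted(p)) for p in parents))


def random_theta(
    dag: Dag,
    seed=0,
    root_range: tuple[float, float] = (0.2, 0.6),
    lo: float = 0.1,
    hi: float = 0.9,
) -> list[np.ndarray]:
    """Strong-contrast theta tables: root frequency uniform in
    ``root_range``; for a node with parents, the mutation probability rises
    linearly from ``lo`` (no parent mutated) to ``hi`` (all mutated), so
    every parent matters."""
    rng = np.random.default_rng(seed)
    tables = []
    for ps in dag.parents:
        m = len(ps)
        if m == 0:
            tables.append(np.array([rng.uniform(*root_range)]))
            continue
        idx = np.arange(2**m)
        active = np.array([bin(i).count("1") for i in idx])
        tables.append(lo + (hi - lo) * active / m)
    return tables


def sample_profiles(dag: Dag, theta: list[np.ndarray], N: int, seed=0) -> np.ndarray:
    """Ancestral sampling in topological order; returns an (N, n) binary
    matrix whose conditional frequencies converge to theta."""
    rng = np.random.default_rng(seed)
    D = np.zeros((N, dag.n), dtype=np.int8)
    for v in dag.topological_order():
        idx = parent_config_index(D, dag.parents[v])
        p = np.asarray(theta[v], float)[idx]
        D[:, v] = rng.random(N) < p
    return D


def sample_mixture(
    truth: GroundTruth, N: int, seed=0
) -> tuple[MutationMatrix, np.ndarray]:
    """Draw cluster labels from Categorical(tau), then profiles from each
    cluster's network.  Returns the matrix and the true labels."""
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    label_ss, *cluster_ss = ss.spawn(truth.K + 1)
    rng = np.random.default_rng(label_ss)
    labels = rng.choice(truth.K, size=N, p=truth.tau)
    D = np.zeros((N, truth.n), dtype=np.int8)
    for k in range(truth.K):
        idx = np.flatnonzero(labels == k)
        if len(idx):
            D[idx] = sample_profiles(
                truth.dags[k], truth.thetas[k], len(idx), seed=cluster_ss[k]
            )
    mm = MutationMatrix(
        [f"S{i:05d}" for i in range(N)], list(truth.gene_names), D
    )
    return mm, labels


def corrupt_prior(
    true_edges: set[frozenset[int]],
    keep_frac: float,
    spurious_count: int,
    gene_universe: list[str],
    seed=0,
) -> PriorNetwork:
    """Imperfect functional prior: keep a fraction of the true skeleton
    edges and add random spurious pairs (emulating an incomplete, noisy
    interaction database)."""
    rng = np.random.default_rng(seed)
    n = len(gene_universe)
    ordered = sorted(tuple(sorted(e)) for e in true_edges)
    n_keep = int(round(keep_frac * len(ordered)))
    kept_idx = rng.choice(len(ordered), size=n_keep, replace=False) if n_keep else []
    edges = {
        frozenset((gene_universe[a], gene_universe[b]))
        for a, b in (ordered[i] for i in sorted(kept_idx))
    }
    existing = {frozenset(e) for e in ordered}
    added = 0
    while added < spurious_count:
        a, b = rng.integers(n), rng.integers(n)
        if a == b:
            continue
        pair = frozenset((int(a), int(b)))
        if pair in existing:
            continue
        name_pair = frozenset((gene_universe[a], gene_universe[b]))
        if name_pair in edges:
            continue
        edges.add(name_pair)
        added += 1
    return PriorNetwork(edges)


def sample_clinical(
    labels: np.ndarray,
    baseline_hazard: float = 1.0 / 365.0,
    log_hr_per_cluster: np.ndarray | None = None,
    censor_rate: float = 0.3,
    seed=0,
    cancer_types: tuple[str, ...] = ("typeA", "typeB", "typeC"),
    sample_ids: list[str] | None = None,
) -> ClinicalTable:
    """Clinical table with cluster-specific exponential survival.

    Event times are exponential with hazard ``baseline_hazard *
    exp(log_hr[cluster])``; censoring is an independent exponential whose
    rate is tuned so roughly ``censor_rate`` of samples are censored
    (``censor_rate=0`` observes every event).  Ages are normal (mean 60,
    sd 10), stages and cancer types categorical, independent of survival.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    N = len(labels)
    if log_hr_per_cluster is None:
        log_hr_per_cluster = np.zeros(int(labels.max()) + 1)
    haz = baseline_hazard * np.exp(np.asarray(log_hr_per_cluster)[labels])
    t_event = rng.exponential(1.0 / haz)
    if censor_rate > 0:
        c_rate = baseline_hazard * censor_rate / (1.0 - censor_rate)
        t_cens = rng.exponential(1.0 / c_rate, size=N)
    else:
        t_cens = np.full(N, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    frame = pd.DataFrame(
        {
            "sample": sample_ids if sample_ids is not None else [f"S{i:05d}" for i in range(N)],
            "age": np.clip(rng.normal(60, 10, N), 20, 95),
            "stage": rng.choice(STAGE_LEVELS, size=N, p=(0.3, 0.25, 0.2, 0.1, 0.15)),
            "cancer_type": rng.choice(cancer_types, size=N),
            "time": time,
            "event": event,
            "cluster": labels.astype(str),
        }
    )
    return ClinicalTable(frame)


# ---------------------------------------------------------------------------
# named fixtures


def bernoulli_mixture_truth(
    K: int = 3,
    n: int = 20,
    genes_per_cluster: int = 5,
    base: float = 0.05,
    signature: float = 0.75,
    tau: np.ndarray | None = None,
) -> GroundTruth:
    """Planted frequency-only mixture: cluster k raises its own block of
    ``genes_per_cluster`` signature genes from ``base`` to ``signature``
    (separation 0.5 by default); all graphs empty."""
    if tau is None:
        tau = np.array([0.45, 0.35, 0.20])[:K]
        tau = tau / tau.sum()
    dags, thetas = [], []
    for k in range(K):
        theta = np.full(n, base)
        theta[k * genes_per_cluster : (k + 1) * genes_per_cluster] = signature
        dags.append(Dag.empty(n))
        thetas.append([np.array([t]) for t in theta])
    return GroundTruth(dags=dags, thetas=thetas, tau=np.asarray(tau, float))


def opposing_dependence_truth(
    n_pairs: int = 3,
    n_noise: int = 0,
    hi: float = 0.95,
) -> GroundTruth:
    """Two clusters with identical marginals but opposite dependence.

    For each planted pair (A, B): P(A)=0.5 in both clusters; in cluster 0
    the genes co-occur (P(B=1|A=1)=hi, P(B=1|A=0)=1-hi) and in cluster 1
    they are mutually exclusive (roles of hi reversed).  Every marginal is
    exactly 0.5, so frequency-only clustering has no signal at all and only
    the interactions distinguish the clusters.  Optional noise genes are
    independent 0.5 in both clusters.
    """
    lo = 1.0 - hi
    n = 2 * n_pairs + n_noise
    edges = [(2 * p, 2 * p + 1) for p in range(n_pairs)]
    dag = Dag.from_edges(n, edges)
    half = np.array([0.5])
    thetas_co, thetas_ex = [], []
    for v in range(n):
        if v % 2 == 1 and v < 2 * n_pairs:
            thetas_co.append(np.array([lo, hi]))  # B | A=0, A=1
            thetas_ex.append(np.array([hi, lo]))
        else:
            thetas_co.append(half.copy())
            thetas_ex.append(half.copy())
    return GroundTruth(
        dags=[dag, dag],
        thetas=[thetas_co, thetas_ex],
        tau=np.array([0.5, 0.5]),
    )


def strong_signal_dag_truth(n: int = 10, seed: int = 7) -> GroundTruth:
    """Single-cluster network with strong, recoverable edges: a random DAG
    (about six edges, at most two parents) with high-contrast conditionals
    (0.1 to 0.9)."""
    dag = random_dag(n, max_parents=2, edge_prob=0.15, seed=seed)
    theta = random_theta(dag, seed=seed + 1, root_range=(0.3, 0.6), lo=0.1, hi=0.9)
    return GroundTruth(dags=[dag], thetas=[theta], tau=np.array([1.0]))
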