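"""BDe marginal-likelihood scores for binary Bayesian networks.

The state of a node ``X`` with ``m`` parents is Bernoulli with a separate
parameter ``theta_Y`` per parent configuration ``Y``, each with a conjugate
``Beta(alpha, beta)`` prior where ``alpha = beta = chi / 2**(m + 1)``.  The
single pseudocount mass ``chi`` is shared across all nodes.  Integrating the
parameters out gives the decomposable log marginal likelihood

    sum_Y  ln B(alpha + a1_Y, beta + a0_Y) - ln B(alpha, beta)

with ``a1_Y`` (``a0_Y``) the number of rows where ``X = 1`` (``X = 0``) under
configuration ``Y``.  Counts may be fractional: per-row nonnegative weights
(EM responsibilities) simply replace unit counts, and the Beta functions are
evaluated at non-integer arguments via log-Gamma.

Structure prior: an edge-wise factorised penalty.  Every edge costs
``ln(global_penalty)`` and an edge absent from the prior network costs an
additional ``ln(prior_penalty)``, i.e. non-prior edges are penalised by the
configured factor (default 2) and, for display-network learning, all edges
by a stronger global factor (16).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import betaln

from .dag import Dag

__all__ = ["ScoringConfig", "local_bde", "dag_score", "score_table"]


@dataclass(frozen=True)
class ScoringConfig:
    """Hyperparameters of the BDe score and its structure prior.

    chi : pseudocount mass, > 0 (default 1).
    prior_penalty : multiplicative penalty on edges missing from the prior
        network (default 2; 1 disables; only applied when a prior is given).
    global_penalty : multiplicative penalty on every edge (default 1;
        16 for learning the displayed consensus networks).
    max_parents : cap on parent-set size (default 3).
    """

    chi: float = 1.0
    prior_penalty: float = 2.0
    global_penalty: float = 1.0
    max_parents: int = 3

    def __post_init__(self) -> None:
        if not self.chi > 0:
            raise ValueError("chi must be positive")
        if self.prior_penalty < 1 or self.global_penalty < 1:
            raise ValueError("penalty factors must be >= 1")
        if self.max_parents < 0:
            raise ValueError("max_parents must be >= 0")


def parent_config_index(D: np.ndarray, parents: Sequence[int]) -> np.ndarray:
    """Per-row parent-configuration index.

    Binary little-endian over the sorted parent tuple: the smallest parent
    index is the least significant bit.  Fixed convention so that theta
    tables are reproducible; nothing observable depends on it.
    """
    parents = sorted(parents)
    if not parents:
        return np.zeros(D.shape[0], dtype=np.int64)
    cols = D[:, parents].astype(np.int64)
    return cols @ (1 << np.arange(len(parents), dtype=np.int64))


def config_counts(
    D: np.ndarray,
    node: int,
    parents: Sequence[int],
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted counts ``(a1, a0)`` of ``X=1`` / ``X=0`` per parent config."""
    m = len(parents)
    idx = parent_config_index(D, parents)
    x = D[:, node].astype(float)
    w = np.ones(D.shape[0]) if weights is None else np.asarray(weights, dtype=float)
    a1 = np.bincount(idx, weights=w * x, minlength=2**m)
    a0 = np.bincount(idx, weights=w * (1.0 - x), minlength=2**m)
    return a1, a0


def _edge_penalty(
    node: int,
    parents: Sequence[int],
    config: ScoringConfig,
    prior_adjacency: np.ndarray | None,
) -> float:
    pen = len(parents) * np.log(config.global_penalty)
    if prior_adjacency is not None and config.prior_penalty > 1:
        off_prior = sum(1 for p in parents if not prior_adjacency[p, node])
        pen += off_prior * np.log(config.prior_penalty)
    return pen


def local_bde(
    D: np.ndarray,
    node: int,
    parents: Sequence[int],
    config: ScoringConfig = ScoringConfig(),
    prior_adjacency: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> float:
    """Log BDe local score of ``node`` given ``parents`` (plus structure
    prior), on binary data ``D`` (rows = samples)."""
    parents = tuple(sorted(set(int(p) for p in parents)))
    if node in parents:
        raise ValueError("node cannot be its own parent")
    m = len(parents)
    if m > config.max_parents:
        raise ValueError(f"parent set size {m} exceeds max_parents={config.max_parents}")
    a = config.chi / 2 ** (m + 1)
    if D.shape[0] == 0:
        score = 0.0
    else:
        a1, a0 = config_counts(D, node, parents, weights)
        score = float(np.sum(betaln(a + a1, a + a0) - betaln(a, a)))
    return score - _edge_penalty(node, parents, config, prior_adjacency)


def dag_score(
    D: np.ndarray,
    dag: Dag,
    config: ScoringConfig = ScoringConfig(),
    prior_adjacency: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> float:
    """Total log score of a DAG: sum of local scores (decomposability)."""
    return sum(
        local_bde(D, v, ps, config, prior_adjacency, weights)
        for v, ps in enumerate(dag.parents)
    )


def score_table(
    D: np.ndarray,
    config: ScoringConfig = ScoringConfig(),
    prior_adjacency: np.ndarray | None = None,
    skeleton: Mapping[int, set[int]] | None = None,
    weights: np.ndarray | None = None,
    max_table_size: int = 2_000_000,
) -> dict[tuple[int, tuple[int, ...]], float]:
    """Precompute every allowed local score.

    Keys are ``(node, sorted parent tuple)``.  Candidate parents per node are
    its skeleton neighbours (all other nodes when ``skeleton`` is None);
    parent sets range over all subsets up to ``config.max_parents``.  Refuses
    to build tables larger than ``max_table_size`` entries.
    """
    n = D.shape[1]
    candidates = {
        v: sorted(skeleton[v] - {v}) if skeleton is not None else
        [u for u in range(n) if u != v]
        for v in range(n)
    }
    total = 0
    for v in range(n):
        c = len(candidates[v])
        total += sum(
            _ncr(c, k) for k in range(0, min(config.max_parents, c) + 1)
        )
    if total > max_table_size:
        raise ValueError(
            f"score table would hold {total} entries (cap {max_table_size}); "
            "restrict the skeleton or lower max_parents"
        )
    table: dict[tuple[int, tuple[int, ...]], float] = {}
    for v in range(n):
        pool = candidates[v]
        for k in range(0, min(config.max_parents, len(pool)) + 1):
            for ps in itertools.combinations(pool, k):
                table[(v, ps)] = local_bde(D, v, ps, config, prior_adjacency, weights)
    return table


def _ncr(n: int, r: int) -> int:
    from math import comb

    return comb(n, r)
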