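"""Structure learning: MAP search and posterior sampling of DAGs.

For a couple of hundred genes an unrestricted search is hopeless, so the
search space is first cut down to an undirected skeleton: a PC-style
constraint-based sweep with G-squared conditional-independence tests,
optionally expanded by a stochastic score-based sweep that rescues edges the
CI tests missed.  MAP structures come from repeated greedy hill climbing and
posterior samples from a Metropolis-Hastings chain over skeleton-restricted
DAGs (single-edge toggles plus edge reversals).  The sampler's contract is a
correct posterior: on small networks its edge-inclusion frequencies are
validated against exact enumeration (:func:`enumerate_posterior`).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy.special import logsumexp
from scipy.stats import chi2

from .bde_scoring import ScoringConfig, local_bde
from .dag import Dag

logger = logging.getLogger(__name__)

__all__ = [
    "Dag",
    "PosteriorSample",
    "EnumeratedPosterior",
    "initial_skeleton",
    "expand_skeleton",
    "map_dag",
    "sample_posterior",
    "enumerate_posterior",
    "complete_skeleton",
]


@dataclass
class PosteriorSample:
    """A sample of DAGs from a structure posterior, with bookkeeping."""

    dags: list[Dag]
    log_scores: list[float]
    seed: int | None = None
    iterations: int = 0
    acceptance_rate: float = float("nan")
    skeleton: dict[int, set[int]] | None = None

    def __post_init__(self) -> None:
        if not self.dags:
            raise ValueError("posterior sample must contain at least one DAG")
        n = self.dags[0].n
        if any(d.n != n for d in self.dags):
            raise ValueError("all DAGs must share the same node set")

    @property
    def M(self) -> int:
        return len(self.dags)

    @property
    def n(self) -> int:
        return self.dags[0].n

    def edge_frequencies(self) -> np.ndarray:
        """Directed edge-inclusion frequencies, shape (n, n)."""
        F = np.zeros((self.n, self.n))
        for d in self.dags:
            F += d.to_adjacency()
        return F / self.M


def complete_skeleton(n: int) -> dict[int, set[int]]:
    return {v: set(range(n)) - {v} for v in range(n)}


# ---------------------------------------------------------------------------
# constraint-based skeleton


def g2_test(D: np.ndarray, i: int, j: int, cond: tuple[int, ...]) -> float:
    """G-squared conditional-independence test of columns i, j given ``cond``
    on binary data; returns the p-value.  Strata with no observations are
    skipped and do not contribute degrees of freedom."""
    from .bde_scoring import parent_config_index

    strata = parent_config_index(D, cond)
    x, y = D[:, i].astype(int), D[:, j].astype(int)
    g2 = 0.0
    dof = 0
    for s in np.unique(strata):
        sel = strata == s
        tot = sel.sum()
        if tot < 2:
            continue
        obs = np.zeros((2, 2))
        np.add.at(obs, (x[sel], y[sel]), 1.0)
        rows, cols = obs.sum(1), obs.sum(0)
        if (rows == 0).any() or (cols == 0).any():
            continue
        exp = np.outer(rows, cols) / tot
        nz = obs > 0
        g2 += 2.0 * np.sum(obs[nz] * np.log(obs[nz] / exp[nz]))
        dof += 1
    if dof == 0:
        return 1.0
    return float(chi2.sf(g2, dof))


def initial_skeleton(
    D: np.ndarray, alpha_ci: float = 0.05, max_cond: int = 3
) -> dict[int, set[int]]:
    """PC-style skeleton: start complete, remove edge (i, j) whenever some
    conditioning set of size up to ``max_cond`` drawn from current
    neighbourhoods renders them independent at level ``alpha_ci``."""
    if not 0 < alpha_ci < 1:
        raise ValueError("alpha_ci must lie in (0, 1)")
    n = D.shape[1]
    adj = complete_skeleton(n)
    for level in range(max_cond + 1):
        snapshot = {v: set(ns) for v, ns in adj.items()}  # PC-stable
        for i in range(n):
            for j in sorted(adj[i]):
                if j < i:
                    continue
                removed = False
                for base in (snapshot[i] - {j}, snapshot[j] - {i}):
                    if removed or len(base) < level:
                        continue
                    for cond in itertools.combinations(sorted(base), level):
                        if g2_test(D, i, j, cond) > alpha_ci:
                            adj[i].discard(j)
                            adj[j].discard(i)
                            removed = True
                            break
                if removed:
                    continue
    return adj


def _best_local(
    D: np.ndarray,
    node: int,
    pool: list[int],
    config: ScoringConfig,
    prior_adjacency: np.ndarray | None,
    weights: np.ndarray | None,
) -> float:
    best = -np.inf
    for k in range(0, min(config.max_parents, len(pool)) + 1):
        for ps in itertools.combinations(pool, k):
            s = local_bde(D, node, ps, config, prior_adjacency, weights)
            if s > best:
                best = s
    return best


def expand_skeleton(
    D: np.ndarray,
    skeleton: dict[int, set[int]],
    config: ScoringConfig = ScoringConfig(),
    iterations: int = 100,
    seed: int = 0,
    prior_adjacency: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> dict[int, set[int]]:
    """Score-based skeleton expansion.

    Repeatedly picks a random missing pair (i, j) and admits the edge when
    adding j to i's candidate-parent pool (or vice versa) strictly raises the
    best achievable local score.  Returns a superset of the input skeleton;
    deterministic given ``seed``; the input is returned unchanged when
    ``iterations`` is 0.
    """
    rng = np.random.default_rng(seed)
    n = D.shape[1]
    adj = {v: set(ns) for v, ns in skeleton.items()}
    for _ in range(iterations):
        missing = [
            (i, j) for i in range(n) for j in range(i + 1, n) if j not in adj[i]
        ]
        if not missing:
            break
        i, j = missing[rng.integers(len(missing))]
        added = False
        for a, b in ((i, j), (j, i)):
            pool = sorted(adj[a] - {a})
            with_b = sorted(set(pool) | {b})
            base = _best_local(D, a, pool, config, prior_adjacency, weights)
            gain = _best_local(D, a, with_b, config, prior_adjacency, weights)
            if gain > base + 1e-9:
                added = True
                break
        if added:
            adj[i].add(j)
            adj[j].add(i)
    return adj


# ---------------------------------------------------------------------------
# shared machinery for search and sampling


class _ScoreCache:
    """Memoised local scores keyed by (node, parent tuple)."""

    def __init__(self, D, config, prior_adjacency, weights):
        self.D = D
        self.config = config
        self.prior = prior_adjacency
        self.weights = weights
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def __call__(self, node: int, parents: tuple[int, ...]) -> float:
        key = (node, tuple(sorted(parents)))
        if key not in self._cache:
            self._cache[key] = local_bde(
                self.D, node, key[1], self.config, self.prior, self.weights
            )
        return self._cache[key]


def _has_path(children: list[set[int]], src: int, dst: int) -> bool:
    """Directed path src -> dst?  (children[v] = set of v's children)."""
    stack, seen = [src], {src}
    while stack:
        v = stack.pop()
        if v == dst:
            return True
        for c in children[v]:
            if c not in seen:
                seen.add(c)
                stack.append(c)
    return False


def map_dag(
    D: np.ndarray,
    config: ScoringConfig = ScoringConfig(),
    prior_adjacency: np.ndarray | None = None,
    skeleton: dict[int, set[int]] | None = None,
    restarts: int = 5,
    seed: int = 0,
    weights: np.ndarray | None = None,
) -> Dag:
    """Greedy hill climbing for the MAP DAG, restricted to the skeleton.

    Steepest-ascent over single-edge additions, deletions and reversals;
    multiple restarts (the first from the empty graph, the rest from random
    skeleton-consistent DAGs).  Deterministic given ``seed``; ties across
    restarts break towards lexicographically smallest parent sets.
    """
    n = D.shape[1]
    if skeleton is None:
        skeleton = complete_skeleton(n)
    score = _ScoreCache(D, config, prior_adjacency, weights)
    rng = np.random.default_rng(seed)
    pairs = [(u, v) for u in range(n) for v in skeleton[u] if u != v]

    best_dag, best_score = None, -np.inf
    for r in range(max(1, restarts)):
        parents: list[set[int]] = [set() for _ in range(n)]
        if r > 0:
            order = rng.permutation(n)
            rank = {int(v): i for i, v in enumerate(order)}
            for u, v in pairs:
                if rank[u] < rank[v] and len(parents[v]) < config.max_parents:
                    if rng.random() < 0.3:
                        parents[v].add(u)
        children = [set() for _ in range(n)]
        for v in range(n):
            for u in parents[v]:
                children[u].add(v)
        cur = sum(score(v, tuple(parents[v])) for v in range(n))
        improved = True
        while improved:
            improved = False
            best_delta, best_move = 1e-9, None
            for u, v in pairs:
                if u in parents[v]:
                    # delete u -> v
                    d = score(v, tuple(parents[v] - {u})) - score(v, tuple(parents[v]))
                    if d > best_delta:
                        best_delta, best_move = d, ("del", u, v)
                    # reverse u -> v
                    if len(parents[u]) < config.max_parents:
                        children[u].discard(v)
                        ok = not _has_path(children, u, v)
                        children[u].add(v)
                        if ok:
                            d = (
                                score(v, tuple(parents[v] - {u}))
                                - score(v, tuple(parents[v]))
                                + score(u, tuple(parents[u] | {v}))
                                - score(u, tuple(parents[u]))
                            )
                            if d > best_delta:
                                best_delta, best_move = d, ("rev", u, v)
                elif (
                    len(parents[v]) < config.max_parents
                    and not _has_path(children, v, u)
                ):
                    d = score(v, tuple(parents[v] | {u})) - score(v, tuple(parents[v]))
                    if d > best_delta:
                        best_delta, best_move = d, ("add", u, v)
            if best_move is not None:
                op, u, v = best_move
                if op == "add":
                    parents[v].add(u)
                    children[u].add(v)
                elif op == "del":
                    parents[v].discard(u)
                    children[u].discard(v)
                else:
                    parents[v].discard(u)
                    children[u].discard(v)
                    parents[u].add(v)
                    children[v].add(u)
                cur += best_delta
                improved = True
        cand = Dag(n, tuple(tuple(sorted(p)) for p in parents))
        if cur > best_score + 1e-9 or (
            abs(cur - best_score) <= 1e-9
            and best_dag is not None
            and cand.parents < best_dag.parents
        ):
            best_dag, best_score = cand, cur
    return best_dag


def sample_posterior(
    D: np.ndarray,
    config: ScoringConfig = ScoringConfig(),
    prior_adjacency: np.ndarray | None = None,
    skeleton: dict[int, set[int]] | None = None,
    M: int = 100,
    seed: int = 0,
    thin: int = 10,
    burn_frac: float = 0.2,
    reversal_prob: float = 0.2,
    weights: np.ndarray | None = None,
) -> PosteriorSample:
    """Metropolis-Hastings sampling of DAGs proportional to exp(score).

    The chain toggles single directed edges (symmetric proposal over the
    skeleton-allowed ordered pairs) and, with probability ``reversal_prob``,
    reverses an existing edge (edge count preserved, hence symmetric).
    Proposals that would create a cycle or exceed ``max_parents`` are
    rejected in place.  The first ``burn_frac`` of iterations are discarded
    and the remainder thinned to ``M`` draws.  Deterministic given ``seed``.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    n = D.shape[1]
    if skeleton is None:
        skeleton = complete_skeleton(n)
    score = _ScoreCache(D, config, prior_adjacency, weights)
    rng = np.random.default_rng(seed)
    pairs = [(u, v) for u in range(n) for v in sorted(skeleton[u]) if u != v]
    if not pairs and n > 1:
        logger.warning("empty skeleton: posterior is a point mass on the empty graph")

    keep = M * thin
    total = int(np.ceil(keep / (1.0 - burn_frac)))
    burn = total - keep

    parents: list[set[int]] = [set() for _ in range(n)]
    children: list[set[int]] = [set() for _ in range(n)]
    locals_ = [score(v, ()) for v in range(n)]
    cur = sum(locals_)
    edges: list[tuple[int, int]] = []

    dags: list[Dag] = []
    scores: list[float] = []
    accepted = 0
    for it in range(total):
        move = None
        if pairs:
            if edges and rng.random() < reversal_prob:
                u, v = edges[rng.integers(len(edges))]
                if len(parents[u]) < config.max_parents:
                    children[u].discard(v)
                    ok = not _has_path(children, u, v)
                    children[u].add(v)
                    if ok:
                        delta = (
                            score(v, tuple(parents[v] - {u}))
                            - locals_[v]
                            + score(u, tuple(parents[u] | {v}))
                            - locals_[u]
                        )
                        move = ("rev", u, v, delta)
            else:
                u, v = pairs[rng.integers(len(pairs))]
                if u in parents[v]:
                    delta = score(v, tuple(parents[v] - {u})) - locals_[v]
                    move = ("del", u, v, delta)
                elif (
                    len(parents[v]) < config.max_parents
                    and not _has_path(children, v, u)
                ):
                    delta = score(v, tuple(parents[v] | {u})) - locals_[v]
                    move = ("add", u, v, delta)
        if move is not None:
            op, u, v, delta = move
            if np.log(rng.random()) < delta:
                accepted += 1
                if op == "add":
                    parents[v].add(u)
                    children[u].add(v)
                    edges.append((u, v))
                    locals_[v] = score(v, tuple(parents[v]))
                elif op == "del":
                    parents[v].discard(u)
                    children[u].discard(v)
                    edges.remove((u, v))
                    locals_[v] = score(v, tuple(parents[v]))
                else:
                    parents[v].discard(u)
                    children[u].discard(v)
                    parents[u].add(v)
                    children[v].add(u)
                    edges.remove((u, v))
                    edges.append((v, u))
                    locals_[v] = score(v, tuple(parents[v]))
                    locals_[u] = score(u, tuple(parents[u]))
                cur = sum(locals_)
        if it >= burn and (it - burn) % thin == thin - 1:
            dags.append(Dag(n, tuple(tuple(sorted(p)) for p in parents)))
            scores.append(cur)
    rate = accepted / total if total else float("nan")
    if rate < 0.01:
        logger.warning("low MCMC acceptance rate %.3f; check mixing", rate)
    return PosteriorSample(
        dags=dags,
        log_scores=scores,
        seed=seed,
        iterations=total,
        acceptance_rate=rate,
        skeleton=skeleton,
    )


# ---------------------------------------------------------------------------
# exact enumeration (test oracle, n <= 5)


@dataclass
class EnumeratedPosterior:
    """Exact structure posterior by exhaustive enumeration of DAGs."""

    dags: list[Dag]
    log_weights: np.ndarray  # normalised log posterior probabilities
    edge_probs: np.ndarray = field(default=None)  # (n, n) directed
    log_evidence: float = 0.0

    @property
    def n(self) -> int:
        return self.dags[0].n


def enumerate_posterior(
    D: np.ndarray,
    config: ScoringConfig = ScoringConfig(),
    prior_adjacency: np.ndarray | None = None,
) -> EnumeratedPosterior:
    """Exact posterior over all DAGs (parent sets capped at ``max_parents``).

    Enumerates every combination of per-node parent sets and keeps the
    acyclic ones.  Exhaustive enumeration is only feasible for very small
    networks; refuses n > 5.
    """
    n = D.shape[1]
    if n > 5:
        raise ValueError("exact enumeration is limited to n <= 5")
    others = [[u for u in range(n) if u != v] for v in range(n)]
    node_masks: list[list[int]] = []
    node_scores: list[dict[int, float]] = []
    for v in range(n):
        masks, sc = [], {}
        for k in range(0, min(config.max_parents, n - 1) + 1):
            for ps in itertools.combinations(others[v], k):
                mask = sum(1 << p for p in ps)
                masks.append(mask)
                sc[mask] = local_bde(D, v, ps, config, prior_adjacency)
        node_masks.append(masks)
        node_scores.append(sc)

    def acyclic(masks: tuple[int, ...]) -> bool:
        placed = 0
        todo = set(range(n))
        while todo:
            ready = [v for v in todo if masks[v] & ~placed == 0]
            if not ready:
                return False
            for v in ready:
                placed |= 1 << v
                todo.discard(v)
        return True

    dags: list[Dag] = []
    logs: list[float] = []
    for combo in itertools.product(*node_masks):
        if not acyclic(combo):
            continue
        s = sum(node_scores[v][combo[v]] for v in range(n))
        parents = tuple(
            tuple(p for p in range(n) if combo[v] >> p & 1) for v in range(n)
        )
        dags.append(Dag(n, parents))
        logs.append(s)
    logs_arr = np.array(logs)
    log_z = float(logsumexp(logs_arr))
    log_w = logs_arr - log_z
    w = np.exp(log_w)
    probs = np.zeros((n, n))
    for dag, wt in zip(dags, w):
        probs += wt * dag.to_adjacency()
    return EnumeratedPosterior(
        dags=dags, log_weights=log_w, edge_probs=probs, log_evidence=log_z
    )


def n_dags(n: int) -> int:
    """Number of labelled DAGs on n nodes (Robinson's recurrence)."""
    a = [1]
    for m in range(1, n + 1):
        a.append(
            sum((-1) ** (k + 1) * comb(m, k) * 2 ** (k * (m - k)) * a[m - k]
                for k in range(1, m + 1))
        )
    return a[n]
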