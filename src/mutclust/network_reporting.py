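"""Consensus-network summaries of posterior DAG samples.

A posterior sample of M DAGs is condensed into the displayed network: an
unordered gene pair is a consensus edge when it appears (in either
orientation) in at least half of the DAGs; its direction is reported only
when one orientation clearly dominates, and its sign (co-occurrence vs
mutual exclusivity) is the sign of the smoothed log odds ratio of the 2x2
mutation table.  Gene display ranking multiplies a gene's consensus
connection count by its mutation frequency.  The overlap of the learned
union network with an external functional-interaction network is assessed
by a gene-label permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .bde_scoring import config_counts
from .structure_search import PosteriorSample

__all__ = [
    "ConsensusEdge",
    "ConsensusNetwork",
    "consensus_edges",
    "edge_sign",
    "rank_genes",
    "hub_counts",
    "prior_overlap_test",
    "consensus_to_frame",
    "consensus_to_graphml",
]


@dataclass(frozen=True)
class ConsensusEdge:
    a: int
    b: int  # a < b
    frequency: float  # fraction of DAGs containing the pair (any direction)
    direction: str  # 'a->b', 'b->a' or 'undirected'


@dataclass
class ConsensusNetwork:
    """Thresholded edge summary of a posterior DAG sample."""

    n: int
    edges: list[ConsensusEdge]
    threshold: float
    pair_frequencies: np.ndarray  # (n, n) symmetric, all pairs

    def connection_counts(self) -> np.ndarray:
        counts = np.zeros(self.n, dtype=int)
        for e in self.edges:
            counts[e.a] += 1
            counts[e.b] += 1
        return counts

    def edge_pairs(self) -> set[frozenset[int]]:
        return {frozenset((e.a, e.b)) for e in self.edges}


def consensus_edges(
    posterior: PosteriorSample,
    threshold: float = 0.5,
    direction_fraction: float = 0.75,
) -> ConsensusNetwork:
    """Consensus edges: pairs present in at least ``threshold`` of the M
    DAGs (boundary inclusive), orientation-agnostic.

    A retained pair is reported as directed only when one orientation holds
    in at least ``direction_fraction`` of the DAGs containing it; otherwise
    the direction cannot be inferred and the edge is undirected.
    """
    n = posterior.n
    fwd = np.zeros((n, n))
    for dag in posterior.dags:
        fwd += dag.to_adjacency()
    fwd /= posterior.M
    pair = fwd + fwd.T
    edges = []
    for a in range(n):
        for b in range(a + 1, n):
            f = pair[a, b]
            if f + 1e-12 < threshold:
                continue
            if fwd[a, b] / f >= direction_fraction:
                direction = "a->b"
            elif fwd[b, a] / f >= direction_fraction:
                direction = "b->a"
            else:
                direction = "undirected"
            edges.append(ConsensusEdge(a, b, float(f), direction))
    return ConsensusNetwork(n, edges, threshold, pair)


def edge_sign(
    D_group: np.ndarray,
    gene_a: int,
    gene_b: int,
    weights: np.ndarray | None = None,
) -> str:
    """'+' for co-occurrence, '-' for mutual exclusivity: the sign of the
    log odds ratio of the 2x2 table with half-pseudocounts per cell."""
    a1, a0 = config_counts(D_group, gene_a, (gene_b,), weights)
    # a1[y] = #(A=1, B=y), a0[y] = #(A=0, B=y)
    n11, n10 = a1[1] + 0.5, a1[0] + 0.5
    n01, n00 = a0[1] + 0.5, a0[0] + 0.5
    log_or = np.log(n11 * n00) - np.log(n10 * n01)
    return "+" if log_or >= 0 else "-"


def model_edge_sign(thetas: Sequence[np.ndarray], dag_parents, child: int, parent: int) -> str:
    """Alternative model-based sign: does the child's mutation probability
    rise when the parent is mutated (averaging over the other parents'
    configurations)?"""
    ps = list(dag_parents[child])
    pos = ps.index(parent)
    table = np.asarray(thetas[child])
    idx = np.arange(table.size)
    on = (idx >> pos) & 1 == 1
    return "+" if table[on].mean() >= table[~on].mean() else "-"


def rank_genes(
    consensus: ConsensusNetwork,
    frequencies: np.ndarray,
    gene_names: Sequence[str] | None = None,
    top_n: int = 20,
) -> list[int] | list[str]:
    """Display ranking: connection count times mutation frequency, keeping
    the ``top_n`` largest products; ties break by higher frequency, then
    lexicographically (by name if given, else by index)."""
    counts = consensus.connection_counts()
    freqs = np.asarray(frequencies, float)
    scores = counts * freqs
    names = list(gene_names) if gene_names is not None else list(range(consensus.n))
    order = sorted(
        range(consensus.n), key=lambda j: (-scores[j], -freqs[j], str(names[j]))
    )
    top = order[: top_n]
    return [names[j] for j in top]


def hub_counts(networks: Sequence[ConsensusNetwork]) -> np.ndarray:
    """Per-gene total number of consensus connections summed over the group
    networks (how the overall hub genes are counted)."""
    if not networks:
        raise ValueError("need at least one consensus network")
    n = networks[0].n
    total = np.zeros(n, dtype=int)
    for net in networks:
        if net.n != n:
            raise ValueError("all networks must share the gene universe")
        total += net.connection_counts()
    return total


def prior_overlap_test(
    union_edges: set[frozenset[int]],
    prior_edges: set[frozenset[int]],
    n_genes: int,
    n_perm: int = 100_000,
    seed=0,
) -> tuple[int, float]:
    """Permutation test of the overlap between a learned union network and
    a functional prior network over the same gene universe.

    The observed statistic is the number of shared unordered edges; the null
    distribution permutes the gene labels of the prior network.  Returns
    (observed overlap, empirical p) with the add-one correction
    p = (1 + #{permuted overlap >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    adj = np.zeros((n_genes, n_genes), dtype=bool)
    for e in union_edges:
        a, b = tuple(e)
        adj[a, b] = adj[b, a] = True
    pe = np.array([tuple(sorted(e)) for e in prior_edges], dtype=int).reshape(-1, 2)
    observed = int(adj[pe[:, 0], pe[:, 1]].sum()) if len(pe) else 0
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n_genes)
        if len(pe) and adj[perm[pe[:, 0]], perm[pe[:, 1]]].sum() >= observed:
            exceed += 1
        elif not len(pe):
            exceed += 1  # degenerate: empty prior always ties
    p = (1 + exceed) / (1 + n_perm)
    return observed, float(p)


def consensus_to_frame(
    consensus: ConsensusNetwork,
    D_group: np.ndarray,
    gene_names: Sequence[str],
    weights: np.ndarray | None = None,
):
    """Edge table (gene_a, gene_b, frequency, direction, sign) for export."""
    import pandas as pd

    rows = []
    for e in consensus.edges:
        direction = {
            "a->b": f"{gene_names[e.a]}->{gene_names[e.b]}",
            "b->a": f"{gene_names[e.b]}->{gene_names[e.a]}",
            "undirected": "undirected",
        }[e.direction]
        rows.append(
            {
                "gene_a": gene_names[e.a],
                "gene_b": gene_names[e.b],
                "frequency": e.frequency,
                "direction": direction,
                "sign": edge_sign(D_group, e.a, e.b, weights),
            }
        )
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "frequency", "direction", "sign"])


def consensus_to_graphml(
    consensus: ConsensusNetwork,
    D_group: np.ndarray,
    gene_names: Sequence[str],
    path,
    weights: np.ndarray | None = None,
) -> None:
    """Write the consensus network as GraphML (undirected graph; direction,
    frequency and sign stored as edge attributes, mutation frequency as a
    node attribute)."""
    import networkx as nx

    g = nx.Graph()
    freqs = np.asarray(D_group, float).mean(axis=0)
    for j, name in enumerate(gene_names):
        g.add_node(name, frequency=float(freqs[j]))
    for e in consensus.edges:
        g.add_edge(
            gene_names[e.a],
            gene_names[e.b],
            frequency=e.frequency,
            direction=e.direction,
            sign=edge_sign(D_group, e.a, e.b, weights),
        )
    nx.write_graphml(g, path)
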