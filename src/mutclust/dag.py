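"""Directed acyclic graphs over a fixed set of binary nodes.

A :class:`Dag` stores, for each node, the sorted tuple of its parent
indices.  The representation is immutable and hashable so graphs can be
used as dictionary keys (memoised local scores, cycle detection in the
clustering loop).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

__all__ = ["Dag", "CycleError"]


class CycleError(ValueError):
    """Raised when a graph that must be acyclic contains a directed cycle."""


def _topological_order(parents: tuple[tuple[int, ...], ...]) -> list[int]:
    """Kahn's algorithm; raises :class:`CycleError` on a cycle."""
    n = len(parents)
    remaining = set(range(n))
    placed: set[int] = set()
    order: list[int] = []
    while remaining:
        ready = [v for v in remaining if placed.issuperset(parents[v])]
        if not ready:
            raise CycleError("graph contains a directed cycle")
        for v in sorted(ready):
            order.append(v)
            placed.add(v)
            remaining.discard(v)
    return order


@dataclass(frozen=True)
class Dag:
    """A labelled DAG on nodes ``0 .. n-1`` given by per-node parent sets."""

    n: int
    parents: tuple[tuple[int, ...], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("a DAG needs at least one node")
        if not self.parents:
            object.__setattr__(self, "parents", tuple(() for _ in range(self.n)))
        if len(self.parents) != self.n:
            raise ValueError("parents must list one tuple per node")
        norm = []
        for v, ps in enumerate(self.parents):
            ps = tuple(sorted(set(int(p) for p in ps)))
            if v in ps:
                raise ValueError(f"node {v} cannot be its own parent")
            if any(p < 0 or p >= self.n for p in ps):
                raise ValueError("parent index out of range")
            norm.append(ps)
        object.__setattr__(self, "parents", tuple(norm))
        _topological_order(self.parents)  # acyclicity check

    @classmethod
    def empty(cls, n: int) -> "Dag":
        return cls(n)

    @classmethod
    def from_edges(cls, n: int, edges: Iterable[tuple[int, int]]) -> "Dag":
        """Build from ``(parent, child)`` pairs."""
        ps: list[list[int]] = [[] for _ in range(n)]
        for u, v in edges:
            ps[v].append(u)
        return cls(n, tuple(tuple(p) for p in ps))

    def edges(self) -> Iterator[tuple[int, int]]:
        """Iterate ``(parent, child)`` pairs."""
        for v, ps in enumerate(self.parents):
            for u in ps:
                yield (u, v)

    @property
    def num_edges(self) -> int:
        return sum(len(ps) for ps in self.parents)

    def skeleton_pairs(self) -> set[frozenset[int]]:
        """Unordered node pairs connected by an edge in either direction."""
        return {frozenset((u, v)) for u, v in self.edges()}

    def topological_order(self) -> list[int]:
        return _topological_order(self.parents)

    def to_adjacency(self) -> np.ndarray:
        """Boolean matrix ``A[u, v] = True`` iff the edge ``u -> v`` exists."""
        A = np.zeros((self.n, self.n), dtype=bool)
        for u, v in self.edges():
            A[u, v] = True
        return A

    def with_edge(self, u: int, v: int) -> "Dag":
        """New DAG with ``u -> v`` added (validates acyclicity)."""
        ps = list(self.parents)
        ps[v] = tuple(sorted(set(ps[v]) | {u}))
        return Dag(self.n, tuple(ps))

    def without_edge(self, u: int, v: int) -> "Dag":
        ps = list(self.parents)
        ps[v] = tuple(p for p in ps[v] if p != u)
        return Dag(self.n, tuple(ps))
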