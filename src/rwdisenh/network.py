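"""Shared weighted-network container.

Both homogeneous networks used by the toolkit — the disease similarity
network (real-valued similarity weights) and the enhancer functional
interaction network (0/1 adjacency) — are symmetric graphs over a single
node type. This module provides the one in-memory representation both use:
an ordered node list plus a dense symmetric adjacency matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = ["WeightedNetwork"]


@dataclass
class WeightedNetwork:
    """Symmetric weighted graph over one node type.

    Parameters
    ----------
    nodes
        Ordered node identifiers; positions index into ``W``.
    W
        Dense symmetric adjacency matrix with zero diagonal and
        non-negative entries. ``W[i, j] > 0`` means an edge of that weight
        between ``nodes[i]`` and ``nodes[j]``.
    """

    nodes: tuple[str, ...]
    W: np.ndarray
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.nodes = tuple(self.nodes)
        W = np.asarray(self.W, dtype=float)
        if W.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError(
                f"adjacency shape {W.shape} does not match {len(self.nodes)} nodes"
            )
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node identifiers")
        if np.any(W < 0):
            raise ValueError("negative edge weights are not allowed")
        if not np.allclose(W, W.T):
            raise ValueError("adjacency matrix must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("self-edges are not allowed")
        self.W = W
        self.index = {n: i for i, n in enumerate(self.nodes)}

    # -- construction -----------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        nodes: Sequence[str],
        edges: Iterable[tuple[str, str, float]],
    ) -> "WeightedNetwork":
        """Build from an undirected weighted edge list.

        ``nodes`` may include isolated nodes; every edge endpoint must be
        listed in ``nodes``.
        """
        nodes = tuple(nodes)
        idx = {n: i for i, n in enumerate(nodes)}
        W = np.zeros((len(nodes), len(nodes)))
        for u, v, w in edges:
            if u not in idx or v not in idx:
                missing = u if u not in idx else v
                raise KeyError(f"edge endpoint {missing!r} not in node set")
            if u == v:
                raise ValueError(f"self-edge on {u!r}")
            W[idx[u], idx[v]] = w
            W[idx[v], idx[u]] = w
        return cls(nodes, W)

    # -- queries ----------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.W, k=1)))

    def degree(self, node: str) -> int:
        return int(np.count_nonzero(self.W[self.index[node]]))

    def neighbors(self, node: str) -> frozenset[str]:
        row = self.W[self.index[node]]
        return frozenset(self.nodes[j] for j in np.nonzero(row)[0])

    def weight(self, u: str, v: str) -> float:
        return float(self.W[self.index[u], self.index[v]])

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Yield each undirected edge once, in node-index order."""
        iu, ju = np.nonzero(np.triu(self.W, k=1))
        for i, j in zip(iu.tolist(), ju.tolist()):
            yield self.nodes[i], self.nodes[j], float(self.W[i, j])

    def edge_set(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset((u, v)) for u, v, _ in self.edges())

    def subgraph(self, keep: Iterable[str]) -> "WeightedNetwork":
        """Restrict to ``keep``, preserving the order in which it lists nodes."""
        keep = [n for n in dict.fromkeys(keep) if n in self.index]
        sel = [self.index[n] for n in keep]
        return WeightedNetwork(tuple(keep), self.W[np.ix_(sel, sel)])
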