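"""Assembly of the heterogeneous disease-enhancer network.

The heterogeneous network stacks the enhancer functional interaction
network (W_E), the disease similarity network (W_D), and the bipartite
known-association matrix (W_ED) into one transition operator

    W' = [ W_E'   W_ED' ]
         [ W_DE'  W_D'  ]

with enhancers indexed first. A walker at a node with both intra- and
inter-subnetwork links crosses between subnetworks with jumping
probability ``lambda`` and stays within its subnetwork with probability
``1 - lambda``; a node with links of only one kind spends its full unit of
outgoing mass on them, so every connected node's outgoing probability
sums to exactly 1. Rows of the printed blocks are out-probabilities
(FROM row TO column); the stored operator is the transpose, applied to
column probability vectors so that diffusion conserves mass.

Seed (initial-probability) vectors: the homogeneous form spreads mass
uniformly over the source set S; the heterogeneous form places ``eta`` on
the disease of interest and ``(1 - eta)/|S'|`` on each of its known
enhancers. When the disease has no usable known enhancers (S' empty) the
whole unit of mass goes to the disease — the degenerate rule that lets
leave-one-out validation cover diseases with a single known enhancer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io_formats import AssociationTable
from .network import WeightedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "BipartiteAssociations",
    "HeteroTransition",
    "SeedConfig",
    "homogeneous_transition",
    "build_hetero_transition",
    "seed_vector_homogeneous",
    "seed_vector_hetero",
]

ENHANCER = "enhancer"
DISEASE = "disease"


@dataclass
class BipartiteAssociations:
    """Known disease-enhancer links as an enhancer x disease 0/1 matrix."""

    enhancers: tuple[str, ...]
    diseases: tuple[str, ...]
    W: np.ndarray  # shape (n_enhancers, n_diseases), entries in {0, 1}

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.shape != (len(self.enhancers), len(self.diseases)):
            raise ValueError("association matrix shape does not match index sets")
        if not np.isin(W, (0.0, 1.0)).all():
            raise ValueError("association matrix entries must be 0 or 1")
        self.W = W

    @classmethod
    def from_table(
        cls,
        table: AssociationTable,
        enhancer_nodes: Sequence[str],
        disease_nodes: Sequence[str],
    ) -> "BipartiteAssociations":
        """Restrict associations to nodes present in both networks.

        Pairs whose enhancer is absent from the enhancer network or whose
        disease is absent from the disease network are dropped (counts
        logged), mirroring the removal of out-of-network entities when the
        heterogeneous network is assembled.
        """
        enh = tuple(enhancer_nodes)
        dis = tuple(disease_nodes)
        ei = {e: i for i, e in enumerate(enh)}
        di = {d: j for j, d in enumerate(dis)}
        W = np.zeros((len(enh), len(dis)))
        dropped = 0
        for d, e in table.pairs:
            if e in ei and d in di:
                W[ei[e], di[d]] = 1.0
            else:
                dropped += 1
        kept = int(W.sum())
        logger.info(
            "associations restricted to networks: %d kept, %d dropped", kept, dropped
        )
        return cls(enh, dis, W)

    @property
    def n_associations(self) -> int:
        return int(self.W.sum())


def _row_normalize(W: np.ndarray) -> np.ndarray:
    """Divide each row by its sum; zero rows stay zero (dangling)."""
    W = np.asarray(W, dtype=float)
    if np.any(W < 0):
        raise ValueError("negative entries in adjacency matrix")
    sums = W.sum(axis=1, keepdims=True)
    out = np.divide(W, sums, out=np.zeros_like(W), where=sums > 0)
    return out


def homogeneous_transition(W: np.ndarray) -> np.ndarray:
    """Column-stochastic walk operator of a homogeneous network.

    Rows of ``W`` are normalized by their sums (zero rows kept zero) and
    the result is transposed so it applies to column probability vectors:
    ``p_next = T @ p`` conserves mass on non-dangling support.
    """
    return _row_normalize(W).T


@dataclass
class HeteroTransition:
    """Assembled heterogeneous walk operator plus its node index.

    ``T`` is column-stochastic on connected nodes (``T[:, i]`` sums to 1
    unless node ``i`` is isolated). ``node_index[i]`` is the
    ``(node_type, node_id)`` at matrix position ``i``; enhancers occupy
    positions ``0..n_enh-1``, diseases the rest.
    """

    T: np.ndarray
    node_index: tuple[tuple[str, str], ...]
    lam: float
    n_enh: int
    position: dict[tuple[str, str], int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.position = {key: i for i, key in enumerate(self.node_index)}

    @property
    def n_nodes(self) -> int:
        return len(self.node_index)

    @property
    def enhancer_positions(self) -> np.ndarray:
        return np.arange(self.n_enh)

    @property
    def disease_positions(self) -> np.ndarray:
        return np.arange(self.n_enh, self.n_nodes)

    @property
    def enhancer_ids(self) -> tuple[str, ...]:
        return tuple(nid for _, nid in self.node_index[: self.n_enh])

    @property
    def disease_ids(self) -> tuple[str, ...]:
        return tuple(nid for _, nid in self.node_index[self.n_enh :])

    def outgoing_mass(self) -> np.ndarray:
        """Total outgoing transition probability per node (column sums)."""
        return self.T.sum(axis=0)


def build_hetero_transition(
    W_E: WeightedNetwork,
    W_D: WeightedNetwork,
    assoc: BipartiteAssociations,
    lam: float = 0.5,
) -> HeteroTransition:
    """Assemble the heterogeneous transition operator.

    For an enhancer with both intra-network edges and disease links, the
    intra row carries ``1 - lam`` and the bipartite row ``lam`` (and
    symmetrically for diseases). A node with links of a single kind gives
    them its whole outgoing mass, keeping the operator stochastic on all
    connected nodes. Nodes with no links at all keep zero rows and are
    handled at walk time by dangling-mass redirection.
    """
    if not (0 < lam < 1):
        raise ValueError(f"lambda must be in (0, 1), got {lam}")
    if assoc.enhancers != W_E.nodes or assoc.diseases != W_D.nodes:
        raise ValueError(
            "association index sets must match the network node orders; "
            "use BipartiteAssociations.from_table to restrict"
        )
    ne, nd = len(assoc.enhancers), len(assoc.diseases)
    rn_E = _row_normalize(W_E.W)
    rn_D = _row_normalize(W_D.W)
    rn_ED = _row_normalize(assoc.W)
    rn_DE = _row_normalize(assoc.W.T)

    e_has_intra = W_E.W.sum(axis=1) > 0
    e_has_inter = assoc.W.sum(axis=1) > 0
    d_has_intra = W_D.W.sum(axis=1) > 0
    d_has_inter = assoc.W.sum(axis=0) > 0

    def _scale(has_intra, has_inter):
        intra = np.where(has_intra & has_inter, 1.0 - lam, 1.0)
        inter = np.where(has_intra & has_inter, lam, 1.0)
        return intra[:, None], inter[:, None]

    e_intra, e_inter = _scale(e_has_intra, e_has_inter)
    d_intra, d_inter = _scale(d_has_intra, d_has_inter)

    R = np.zeros((ne + nd, ne + nd))
    R[:ne, :ne] = e_intra * rn_E
    R[:ne, ne:] = e_inter * rn_ED
    R[ne:, :ne] = d_inter * rn_DE
    R[ne:, ne:] = d_intra * rn_D

    node_index = tuple((ENHANCER, e) for e in assoc.enhancers) + tuple(
        (DISEASE, d) for d in assoc.diseases
    )
    return HeteroTransition(R.T, node_index, lam, ne)


@dataclass(frozen=True)
class SeedConfig:
    """Sources for a disease-centric heterogeneous walk.

    ``enhancers`` is S' (the disease's known enhancers, possibly empty);
    ``disease`` the disease of interest; ``eta`` splits the initial mass
    between the disease (eta) and the enhancer seeds (1 - eta);
    ``gamma`` is the restart probability of the walk itself.
    """

    enhancers: tuple[str, ...]
    disease: str
    eta: float = 0.5
    gamma: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.eta < 1):
            raise ValueError(f"eta must be in (0, 1), got {self.eta}")
        if not (0 < self.gamma < 1):
            raise ValueError(f"gamma must be in (0, 1), got {self.gamma}")
        if self.disease is None and not self.enhancers:
            raise ValueError("seed set is empty")


def seed_vector_homogeneous(S: Iterable[str], network: WeightedNetwork) -> np.ndarray:
    """Uniform initial probability 1/|S| over the source set."""
    S = list(dict.fromkeys(S))
    if not S:
        raise ValueError("source set is empty")
    missing = [s for s in S if s not in network.index]
    if missing:
        raise KeyError(f"source nodes not in network: {missing}")
    p0 = np.zeros(network.n_nodes)
    p0[[network.index[s] for s in S]] = 1.0 / len(S)
    return p0


def seed_vector_hetero(
    S_prime: Iterable[str],
    disease: str,
    eta: float,
    hetero: HeteroTransition,
) -> np.ndarray:
    """Initial probabilities: eta on the disease, (1-eta)/|S'| per seed enhancer.

    With ``S'`` empty the full unit of mass goes to the disease (logged) —
    the degenerate rule for diseases with no remaining known enhancers.
    """
    if not (0 < eta < 1):
        raise ValueError(f"eta must be in (0, 1), got {eta}")
    S_prime = list(dict.fromkeys(S_prime))
    dkey = (DISEASE, disease)
    if dkey not in hetero.position:
        raise KeyError(f"disease {disease!r} not in the heterogeneous network")
    p0 = np.zeros(hetero.n_nodes)
    if not S_prime:
        logger.warning(
            "empty enhancer seed set for disease %s; full mass on the disease",
            disease,
        )
        p0[hetero.position[dkey]] = 1.0
        return p0
    for e in S_prime:
        ekey = (ENHANCER, e)
        if ekey not in hetero.position:
            raise KeyError(f"seed enhancer {e!r} not in the heterogeneous network")
        p0[hetero.position[ekey]] = (1.0 - eta) / len(S_prime)
    p0[hetero.position[dkey]] = eta
    return p0
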