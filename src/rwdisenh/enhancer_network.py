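"""Enhancer functional interaction network from shared target genes.

Two enhancers are functionally linked when the overlap of their
target-gene sets is larger than expected by chance. With ``n`` distinct
target genes in the corpus, target-set sizes ``n_i`` and ``n_j``, and
``k`` shared genes, the upper-tail hypergeometric probability

    p = sum_{i=k}^{min(n_i, n_j)} C(n_j, i) C(n - n_j, n_i - i) / C(n, n_i)

is computed for every unordered enhancer pair; pairs with ``p <= alpha``
(default 0.05, no multiple-testing correction) become edges of the
unweighted network W_E. Per-pair test records are retained for audit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .io_formats import TargetMap
from .network import WeightedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapTest",
    "EnhancerNetwork",
    "hypergeometric_overlap_p",
    "build_enhancer_network",
]


@dataclass(frozen=True)
class OverlapTest:
    """One pairwise target-set overlap test."""

    n: int
    n_i: int
    n_j: int
    k: int
    p: float


@dataclass(frozen=True)
class EnhancerNetwork:
    """Unweighted enhancer functional interaction network plus audit trail.

    ``tests`` records every tested pair with a non-empty overlap (k >= 1);
    pairs with k = 0 have p = 1 exactly and are omitted from the audit.
    """

    network: WeightedNetwork
    tests: dict[tuple[str, str], OverlapTest]
    alpha: float
    n_genes: int


def hypergeometric_overlap_p(n: int, n_i: int, n_j: int, k: int) -> float:
    """Upper-tail probability of observing >= k shared genes.

    Symmetric in ``n_i``/``n_j``; ``k = 0`` gives exactly 1.
    """
    if not (0 <= k <= min(n_i, n_j)):
        raise ValueError(f"k={k} outside [0, min(n_i, n_j)={min(n_i, n_j)}]")
    if n_i > n or n_j > n or n_i < 0 or n_j < 0:
        raise ValueError(f"set sizes n_i={n_i}, n_j={n_j} must lie in [0, n={n}]")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, n, n_j, n_i))


def build_enhancer_network(tm: TargetMap, alpha: float = 0.05) -> EnhancerNetwork:
    """Test all unordered enhancer pairs; link those with p <= alpha.

    ``n`` is the number of distinct genes in the supplied target map,
    computed from the input. Isolated enhancers are retained as nodes.
    """
    enhancers = tm.enhancers
    if len(enhancers) < 2:
        raise ValueError("need at least 2 enhancers to build a network")
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    genes = sorted(tm.genes)
    n = len(genes)
    gidx = {g: i for i, g in enumerate(genes)}
    B = np.zeros((len(enhancers), n), dtype=np.int64)
    for r, e in enumerate(enhancers):
        B[r, [gidx[g] for g in tm.targets[e]]] = 1
    sizes = B.sum(axis=1)
    K = B @ B.T  # pairwise shared-target counts
    iu, ju = np.triu_indices(len(enhancers), k=1)
    kk = K[iu, ju]
    # vectorized upper tail; k = 0 pairs are exactly 1 and never edges
    pp = np.ones(len(kk))
    pos = kk > 0
    pp[pos] = hypergeom.sf(kk[pos] - 1, n, sizes[ju[pos]], sizes[iu[pos]])
    tests: dict[tuple[str, str], OverlapTest] = {}
    edges = []
    for i, j, k_ij, p in zip(iu[pos], ju[pos], kk[pos], pp[pos]):
        pair = (enhancers[i], enhancers[j])
        tests[pair] = OverlapTest(n, int(sizes[i]), int(sizes[j]), int(k_ij), float(p))
    for (ei, ej), t in tests.items():
        if t.p <= alpha:
            edges.append((ei, ej, 1.0))
    if alpha >= 1.0:  # k = 0 pairs (p = 1) qualify too
        edges = [(enhancers[i], enhancers[j], 1.0) for i, j in zip(iu, ju)]
    net = WeightedNetwork.from_edges(enhancers, edges)
    logger.info(
        "enhancer network: %d nodes, %d edges (alpha=%g, n=%d genes)",
        net.n_nodes,
        net.n_edges,
        alpha,
        n,
    )
    return EnhancerNetwork(net, tests, alpha, n)
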