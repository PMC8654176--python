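"""Ranking engines: random walk with restart, PageRank with Priors, MaxLink.

All three engines score candidate nodes by their relevance to a source set
and emit a :class:`RankingResult` with average-rank tie handling.

* **RWR** iterates ``P <- (1 - gamma) T P + gamma P0`` on a
  column-stochastic operator until the L1 change drops below tolerance;
  mass arriving at dangling nodes (zero outgoing transitions) is
  redirected to the seed vector so the iteration stays stochastic.
* **PageRank with Priors** is the same restart recurrence driven by the
  out-degree-normalized adjacency (on an undirected network each edge
  counts as two directed links, so the normalization coincides with the
  RWR operator and the two engines agree on symmetric inputs).
* **MaxLink** scores each direct neighbor of the source set by its link
  count to it, discarding candidates whose link count is unsurprising
  given their degree (connection probability >= 0.5, hypergeometric
  point probability by default; an upper-tail variant is available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom, rankdata

from .heterogeneous_network import (
    DISEASE,
    ENHANCER,
    HeteroTransition,
    SeedConfig,
    homogeneous_transition,
    seed_vector_hetero,
    seed_vector_homogeneous,
)
from .network import WeightedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ConvergenceError",
    "RankingResult",
    "rwr",
    "rank_rwdisenh",
    "rank_homogeneous",
    "page_rank_with_priors",
    "rank_prp",
    "rank_prp_hetero",
    "maxlink",
    "maxlink_scores",
]

DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 1000


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach tolerance within the iteration cap."""

    def __init__(self, residual: float, max_iter: int):
        self.residual = residual
        self.max_iter = max_iter
        super().__init__(
            f"no convergence after {max_iter} iterations (last residual {residual:g})"
        )


@dataclass(frozen=True)
class RankingResult:
    """Scores and ranks of candidate nodes relative to a seed set.

    Ranks are a permutation of 1..|C| (average ranks on ties); seeds are
    never candidates. ``iterations``/``residual`` are convergence metadata
    where an iterative engine produced the scores.
    """

    method: str
    scores: dict[str, float]
    seeds: tuple[str, ...]
    candidates: tuple[str, ...]
    ranks: dict[str, float]
    iterations: int | None = None
    residual: float | None = None

    @classmethod
    def from_scores(
        cls,
        method: str,
        scores: Mapping[str, float],
        seeds: Iterable[str],
        candidates: Sequence[str],
        iterations: int | None = None,
        residual: float | None = None,
    ) -> "RankingResult":
        seeds = tuple(dict.fromkeys(seeds))
        candidates = tuple(candidates)
        if set(seeds) & set(candidates):
            raise ValueError("seed and candidate sets must be disjoint")
        values = np.array([scores[c] for c in candidates])
        ranks = rankdata(-values, method="average")
        return cls(
            method,
            {c: float(scores[c]) for c in candidates},
            seeds,
            candidates,
            dict(zip(candidates, ranks.tolist())),
            iterations,
            residual,
        )

    def top(self, k: int = 10) -> tuple[str, ...]:
        order = sorted(self.candidates, key=lambda c: (self.ranks[c], c))
        return tuple(order[:k])


# ---------------------------------------------------------------------------
# Random walk with restart
# ---------------------------------------------------------------------------


def rwr(
    T: np.ndarray,
    p0: np.ndarray,
    gamma: float = 0.5,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[np.ndarray, int, float]:
    """Steady state of ``P <- (1-gamma) (T P + dangling mass * P0) + gamma P0``.

    ``T`` must be column-stochastic on connected nodes; columns summing to
    zero mark dangling nodes, whose incoming probability is redirected to
    the seed vector. Returns ``(P_inf, iterations, final L1 residual)``.
    """
    p0 = np.asarray(p0, dtype=float)
    if abs(p0.sum() - 1.0) > 1e-9:
        raise ValueError(f"initial vector sums to {p0.sum()!r}, expected 1")
    if not (0 < gamma < 1):
        raise ValueError(f"gamma must be in (0, 1), got {gamma}")
    dangling = np.asarray(T).sum(axis=0) < 1e-15
    p = p0.copy()
    for it in range(1, max_iter + 1):
        spill = p[dangling].sum() if dangling.any() else 0.0
        p_next = (1.0 - gamma) * (T @ p + spill * p0) + gamma * p0
        residual = float(np.abs(p_next - p).sum())
        p = p_next
        if residual < tol:
            return p, it, residual
    raise ConvergenceError(residual, max_iter)


def rank_rwdisenh(
    hetero: HeteroTransition,
    seeds: SeedConfig,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> RankingResult:
    """Disease-centric ranking on the heterogeneous network.

    Runs RWR from the combined seed (disease of interest + its known
    enhancers); candidates are all enhancer nodes outside the seed set,
    and disease nodes are excluded from the ranking.
    """
    p0 = seed_vector_hetero(seeds.enhancers, seeds.disease, seeds.eta, hetero)
    p, iters, res = rwr(hetero.T, p0, seeds.gamma, tol, max_iter)
    enh_ids = hetero.enhancer_ids
    scores = {e: float(p[i]) for i, e in enumerate(enh_ids)}
    candidates = tuple(e for e in enh_ids if e not in set(seeds.enhancers))
    return RankingResult.from_scores(
        "rwdisenh", scores, seeds.enhancers + (seeds.disease,), candidates, iters, res
    )


def rank_homogeneous(
    network: WeightedNetwork,
    seeds: Iterable[str],
    gamma: float = 0.5,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    method: str = "rwr-homog",
) -> RankingResult:
    """RWR on a single network; candidates are all non-seed nodes.

    Works for both views: the enhancer functional interaction network
    (disease-centric) and the disease similarity network
    (enhancer-centric). Row normalization makes the ranking invariant to
    a global rescaling of the weights.
    """
    seeds = tuple(dict.fromkeys(seeds))
    T = homogeneous_transition(network.W)
    p0 = seed_vector_homogeneous(seeds, network)
    p, iters, res = rwr(T, p0, gamma, tol, max_iter)
    scores = {node: float(p[i]) for i, node in enumerate(network.nodes)}
    candidates = tuple(n for n in network.nodes if n not in set(seeds))
    return RankingResult.from_scores(method, scores, seeds, candidates, iters, res)


# ---------------------------------------------------------------------------
# PageRank with Priors
# ---------------------------------------------------------------------------


def page_rank_with_priors(
    W: np.ndarray,
    p0: np.ndarray,
    beta: float = 0.7,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[np.ndarray, int, float]:
    """Iterate ``p_i <- (1-beta) sum_{j in in(i)} p_ji p_j + beta p0_i``.

    ``p_ji`` is edge weight over the out-weight of ``j`` (out-degree
    normalization); undirected edges count in both directions. Dangling
    mass is redirected to the prior, as in :func:`rwr`.
    """
    if not (0 < beta < 1):
        raise ValueError(f"beta must be in (0, 1), got {beta}")
    T = homogeneous_transition(np.asarray(W, dtype=float))
    return rwr(T, p0, beta, tol, max_iter)


def rank_prp(
    network: WeightedNetwork,
    seeds: Iterable[str],
    beta: float = 0.7,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> RankingResult:
    """PageRank with Priors on a homogeneous network."""
    seeds = tuple(dict.fromkeys(seeds))
    p0 = seed_vector_homogeneous(seeds, network)
    p, iters, res = page_rank_with_priors(network.W, p0, beta, tol, max_iter)
    scores = {node: float(p[i]) for i, node in enumerate(network.nodes)}
    candidates = tuple(n for n in network.nodes if n not in set(seeds))
    return RankingResult.from_scores("prp", scores, seeds, candidates, iters, res)


def rank_prp_hetero(
    hetero: HeteroTransition,
    seeds: SeedConfig,
    beta: float = 0.7,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> RankingResult:
    """PageRank with Priors on the heterogeneous network.

    The assembled operator replaces the plain adjacency; since its rows
    are already out-normalized, the recurrence reduces to a restart walk
    with back-probability ``beta`` on the same operator, seeded as in the
    disease-centric heterogeneous view.
    """
    p0 = seed_vector_hetero(seeds.enhancers, seeds.disease, seeds.eta, hetero)
    p, iters, res = rwr(hetero.T, p0, beta, tol, max_iter)
    enh_ids = hetero.enhancer_ids
    scores = {e: float(p[i]) for i, e in enumerate(enh_ids)}
    candidates = tuple(e for e in enh_ids if e not in set(seeds.enhancers))
    return RankingResult.from_scores(
        "prp", scores, seeds.enhancers + (seeds.disease,), candidates, iters, res
    )


# ---------------------------------------------------------------------------
# MaxLink
# ---------------------------------------------------------------------------


def maxlink_scores(
    adjacency: np.ndarray,
    nodes: Sequence[str],
    S: Iterable[str],
    *,
    tail: bool = False,
) -> tuple[dict[str, int], dict[str, float], set[str]]:
    """Link counts, connection probabilities, and the retained candidate set.

    Candidates are direct neighbors of ``S`` outside ``S``; each scores
    ``ML(v)`` = number of links to ``S``. The connection probability is
    the hypergeometric point probability of drawing exactly ``ML`` seeds
    among ``deg(v)`` neighbors from ``|V|`` nodes of which ``|S|`` are
    seeds (``tail=True`` uses the upper-tail probability of >= ML
    instead); candidates with probability >= 0.5 are discarded.
    """
    S = list(dict.fromkeys(S))
    idx = {n: i for i, n in enumerate(nodes)}
    missing = [s for s in S if s not in idx]
    if missing:
        raise KeyError(f"source nodes not in network: {missing}")
    if not S:
        raise ValueError("source set is empty")
    A = (np.asarray(adjacency) > 0).astype(float)
    n_nodes = len(nodes)
    s_pos = [idx[s] for s in S]
    ml_all = A[:, s_pos].sum(axis=1)
    deg = A.sum(axis=1)
    ml: dict[str, int] = {}
    prob: dict[str, float] = {}
    retained: set[str] = set()
    for i, v in enumerate(nodes):
        if v in S or ml_all[i] == 0:
            continue
        m, d = int(ml_all[i]), int(deg[i])
        ml[v] = m
        if tail:
            cp = float(hypergeom.sf(m - 1, n_nodes, len(S), d))
        else:
            cp = float(hypergeom.pmf(m, n_nodes, len(S), d))
        prob[v] = cp
        if cp < 0.5:
            retained.add(v)
    return ml, prob, retained


def maxlink(
    network: WeightedNetwork,
    S: Iterable[str],
    *,
    tail: bool = False,
) -> RankingResult:
    """MaxLink ranking of the retained neighbors of ``S``.

    Scores are integer link counts (bounded by ``|S|``); only neighbors
    passing the connection-probability filter are ranked. Non-neighbors
    and discarded neighbors receive no rank here; evaluation places them
    below all ranked candidates, tied.
    """
    S = tuple(dict.fromkeys(S))
    ml, prob, retained = maxlink_scores(network.W, network.nodes, S, tail=tail)
    candidates = tuple(n for n in network.nodes if n in retained)
    scores = {c: float(ml[c]) for c in candidates}
    return RankingResult.from_scores("maxlink", scores, S, candidates)
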