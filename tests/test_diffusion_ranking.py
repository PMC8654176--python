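"""Ranking engines against closed-form and direct linear-solve oracles."""

from __future__ import annotations

import numpy as np
import pytest

from rwdisenh import (
    BipartiteAssociations,
    SeedConfig,
    WeightedNetwork,
    build_hetero_transition,
    homogeneous_transition,
    maxlink,
    page_rank_with_priors,
    rank_homogeneous,
    rank_prp,
    rank_rwdisenh,
    rwr,
    seed_vector_homogeneous,
)
from rwdisenh.diffusion_ranking import ConvergenceError, RankingResult

from conftest import direct_steady_state, random_hetero_parts, random_network


# ---------------------------------------------------------------------------
# RWR core
# ---------------------------------------------------------------------------


def test_single_node_fixed_point():
    p, _, _ = rwr(np.zeros((1, 1)), np.array([1.0]), gamma=0.5)
    assert p == pytest.approx([1.0])


def test_two_node_closed_form():
    """Seeded two-node walk at gamma = 0.5 settles at (2/3, 1/3)."""
    T = np.array([[0.0, 1.0], [1.0, 0.0]])
    p, _, _ = rwr(T, np.array([1.0, 0.0]), gamma=0.5)
    assert p == pytest.approx([2 / 3, 1 / 3], abs=1e-9)


def test_restart_dominated_limit():
    T = homogeneous_transition(random_network(np.random.default_rng(0), 8, 0.4).W)
    p0 = np.zeros(8)
    p0[0] = 1.0
    p, _, _ = rwr(T, p0, gamma=1 - 1e-9)
    assert p == pytest.approx(p0, abs=1e-8)


def test_mass_conserved_with_dangling_nodes():
    rng = np.random.default_rng(1)
    net = random_network(rng, 15, edge_p=0.08)  # likely has isolated nodes
    T = homogeneous_transition(net.W)
    assert (T.sum(axis=0) == 0).any(), "fixture should contain a dangling node"
    p0 = seed_vector_homogeneous([net.nodes[0]], net)
    p, _, _ = rwr(T, p0, gamma=0.3)
    assert p.sum() == pytest.approx(1.0, abs=1e-9)


def test_non_convergence_raises_with_residual():
    T = np.array([[0.0, 1.0], [1.0, 0.0]])
    with pytest.raises(ConvergenceError) as err:
        rwr(T, np.array([1.0, 0.0]), gamma=0.01, max_iter=2)
    assert err.value.residual > 0


@pytest.mark.parametrize("seed", range(10))
def test_rwr_matches_direct_solve(seed):
    rng = np.random.default_rng(seed)
    net = random_network(rng, int(rng.integers(5, 40)), 0.15, weighted=True)
    T = homogeneous_transition(net.W)
    p0 = np.zeros(net.n_nodes)
    p0[: max(1, net.n_nodes // 5)] = 1.0 / max(1, net.n_nodes // 5)
    gamma = float(rng.uniform(0.1, 0.9))
    p, _, _ = rwr(T, p0, gamma)
    assert p == pytest.approx(direct_steady_state(T, p0, gamma), abs=1e-8)


def test_seed_score_monotone_in_gamma():
    rng = np.random.default_rng(5)
    net = random_network(rng, 20, 0.2)
    T = homogeneous_transition(net.W)
    p0 = seed_vector_homogeneous([net.nodes[0]], net)
    prev = -1.0
    for gamma in (0.1, 0.3, 0.5, 0.7, 0.9):
        p, _, _ = rwr(T, p0, gamma)
        assert p[0] >= prev - 1e-12
        prev = p[0]


# ---------------------------------------------------------------------------
# disease-centric heterogeneous ranking
# ---------------------------------------------------------------------------


def _hand_hetero():
    """4 enhancers / 2 diseases: e1-e2-e3 path plus isolated e4."""
    W_E = WeightedNetwork.from_edges(
        ("e1", "e2", "e3", "e4"), [("e1", "e2", 1.0), ("e2", "e3", 1.0)]
    )
    W_D = WeightedNetwork.from_edges(("d1", "d2"), [("d1", "d2", 1.5)])
    B = np.zeros((4, 2))
    B[0, 0] = 1.0  # e1 - d1
    B[2, 1] = 1.0  # e3 - d2
    return W_E, W_D, BipartiteAssociations(W_E.nodes, W_D.nodes, B)


def test_connected_candidate_outranks_isolated():
    W_E, W_D, assoc = _hand_hetero()
    h = build_hetero_transition(W_E, W_D, assoc, 0.5)
    res = rank_rwdisenh(h, SeedConfig(("e1", "e3"), "d1"))
    assert res.ranks["e2"] < res.ranks["e4"]


def test_hetero_scores_match_direct_solve():
    W_E, W_D, assoc = _hand_hetero()
    h = build_hetero_transition(W_E, W_D, assoc, 0.5)
    from rwdisenh import seed_vector_hetero

    p0 = seed_vector_hetero(("e1",), "d1", 0.5, h)
    p, _, _ = rwr(h.T, p0, 0.5)
    assert p == pytest.approx(direct_steady_state(h.T, p0, 0.5), abs=1e-8)


def test_node_order_invariance():
    """Permuting the input node order leaves the ranking unchanged."""
    W_E, W_D, assoc = _hand_hetero()
    h = build_hetero_transition(W_E, W_D, assoc, 0.5)
    res = rank_rwdisenh(h, SeedConfig(("e1",), "d1"))

    order = ("e3", "e1", "e4", "e2")
    W_E2 = W_E.subgraph(order)
    perm = [W_E.nodes.index(e) for e in order]
    assoc2 = BipartiteAssociations(order, W_D.nodes, assoc.W[perm])
    h2 = build_hetero_transition(W_E2, W_D, assoc2, 0.5)
    res2 = rank_rwdisenh(h2, SeedConfig(("e1",), "d1"))
    assert res.ranks == res2.ranks


# ---------------------------------------------------------------------------
# homogeneous ranking
# ---------------------------------------------------------------------------


def test_path_scores_decay_with_distance():
    nodes = tuple(f"v{i}" for i in range(5))
    net = WeightedNetwork.from_edges(
        nodes, [(f"v{i}", f"v{i + 1}", 1.0) for i in range(4)]
    )
    res = rank_homogeneous(net, ["v0"], gamma=0.5)
    scores = [res.scores[f"v{i}"] for i in range(1, 5)]
    assert all(a > b for a, b in zip(scores, scores[1:]))


def test_weight_scale_invariance():
    rng = np.random.default_rng(2)
    net = random_network(rng, 12, 0.3, weighted=True)
    doubled = WeightedNetwork(net.nodes, 2.0 * net.W)
    r1 = rank_homogeneous(net, [net.nodes[0]])
    r2 = rank_homogeneous(doubled, [net.nodes[0]])
    assert r1.ranks == r2.ranks


def test_single_candidate_view():
    net = WeightedNetwork.from_edges(("d1", "d2"), [("d1", "d2", 0.4)])
    res = rank_homogeneous(net, ["d1"])
    assert res.candidates == ("d2",) and res.ranks["d2"] == 1.0


# ---------------------------------------------------------------------------
# PageRank with Priors
# ---------------------------------------------------------------------------


def test_prp_single_node():
    p, _, _ = page_rank_with_priors(np.zeros((1, 1)), np.array([1.0]), beta=0.7)
    assert p == pytest.approx([1.0])


def test_prp_two_node_closed_form():
    """beta = 0.7 on two linked nodes: seed 0.7/0.91, other 0.21/0.91."""
    W = np.array([[0.0, 1.0], [1.0, 0.0]])
    p, _, _ = page_rank_with_priors(W, np.array([1.0, 0.0]), beta=0.7)
    assert p == pytest.approx([0.7 / 0.91, 0.21 / 0.91], abs=1e-9)
    assert p == pytest.approx([0.7692307, 0.2307692], abs=1e-6)


@pytest.mark.parametrize("seed", range(5))
def test_prp_equals_rwr_on_symmetric_networks(seed):
    """On undirected networks the out-degree normalization of PRP equals
    the row normalization of the restart walk, so the recurrences coincide."""
    rng = np.random.default_rng(seed)
    net = random_network(rng, 15, 0.25, weighted=True)
    p0 = seed_vector_homogeneous([net.nodes[0], net.nodes[1]], net)
    beta = 0.7
    p_prp, _, _ = page_rank_with_priors(net.W, p0, beta)
    p_rwr, _, _ = rwr(homogeneous_transition(net.W), p0, beta)
    assert p_prp == pytest.approx(p_rwr, abs=1e-10)


# ---------------------------------------------------------------------------
# MaxLink
# ---------------------------------------------------------------------------


def _seeded_star():
    """10 nodes; candidate c adjacent to all 3 seeds; filler chain."""
    nodes = ("s1", "s2", "s3", "c") + tuple(f"f{i}" for i in range(6))
    edges = [("c", s, 1.0) for s in ("s1", "s2", "s3")]
    edges += [(f"f{i}", f"f{i + 1}", 1.0) for i in range(5)]
    return WeightedNetwork.from_edges(nodes, edges)


def test_maxlink_connection_probability_and_rank():
    net = _seeded_star()
    res = maxlink(net, ["s1", "s2", "s3"])
    # ML = 3 with deg 3 in a 10-node graph: point probability
    # C(3,3) C(7,0) / C(10,3) = 1/120 < 0.5 -> retained, top rank
    assert res.scores["c"] == 3.0
    assert res.ranks["c"] == 1.0
    from scipy.stats import hypergeom

    assert hypergeom.pmf(3, 10, 3, 3) == pytest.approx(1 / 120, abs=1e-15)


def test_maxlink_degree_one_candidate_retained():
    nodes = tuple(f"v{i}" for i in range(10))
    net = WeightedNetwork.from_edges(nodes, [("v0", "v1", 1.0)])
    res = maxlink(net, ["v0"])
    # ML = 1, deg 1, |V| = 10, |S| = 1: C(1,1)C(9,0)/C(10,1) = 1/10 -> kept
    assert res.candidates == ("v1",)
    assert res.scores["v1"] == 1.0


def test_maxlink_non_neighbors_excluded_and_bounded():
    net = _seeded_star()
    res = maxlink(net, ["s1", "s2", "s3"])
    assert "f0" not in res.candidates
    assert all(v == int(v) and v <= 3 for v in res.scores.values())


def test_maxlink_discards_unsurprising_hubs():
    """A candidate linked to 1 of 2 seeds in a tiny graph has point
    probability C(2,1)C(1,0)/C(3,1)... high enough to be discarded."""
    nodes = ("s1", "s2", "c")
    net = WeightedNetwork.from_edges(nodes, [("c", "s1", 1.0)])
    res = maxlink(net, ["s1", "s2"])
    # pmf(1; N=3, K=2, n=1) = 2/3 >= 0.5 -> discarded
    assert res.candidates == ()


def test_maxlink_tail_variant():
    net = _seeded_star()
    from rwdisenh.diffusion_ranking import maxlink_scores

    _, p_point, _ = maxlink_scores(net.W, net.nodes, ["s1", "s2", "s3"])
    _, p_tail, _ = maxlink_scores(net.W, net.nodes, ["s1", "s2", "s3"], tail=True)
    assert p_tail["c"] >= p_point["c"] - 1e-15


def test_maxlink_unknown_seed_errors():
    net = _seeded_star()
    with pytest.raises(KeyError):
        maxlink(net, ["nope"])


# ---------------------------------------------------------------------------
# RankingResult container
# ---------------------------------------------------------------------------


def test_ranks_are_average_on_ties():
    res = RankingResult.from_scores(
        "x", {"a": 0.5, "b": 0.5, "c": 0.1}, ("s",), ("a", "b", "c")
    )
    assert res.ranks == {"a": 1.5, "b": 1.5, "c": 3.0}
    assert sorted(res.ranks.values()) == [1.5, 1.5, 3.0]


def test_seeds_and_candidates_must_be_disjoint():
    with pytest.raises(ValueError):
        RankingResult.from_scores("x", {"a": 1.0}, ("a",), ("a",))
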