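"""Shared fixtures: hand-built toy ontologies and random network factories."""

from __future__ import annotations

import numpy as np
import pytest

from rwdisenh import (
    BipartiteAssociations,
    OntologyGraph,
    WeightedNetwork,
)


@pytest.fixture
def toy_dag() -> OntologyGraph:
    """The 8-gene toy DAG used for hand-checked IC/similarity values.

    root has children c1 and c2; c1 has child L. Direct annotations:
    c1 -> 1 gene, L -> 1 gene, c2 -> 6 genes. Hence f(L)=1, f(c1)=2,
    f(c2)=6, f(root)=8.
    """
    g = OntologyGraph(
        terms=frozenset({"root", "c1", "c2", "L"}),
        parents={
            "root": frozenset(),
            "c1": frozenset({"root"}),
            "c2": frozenset({"root"}),
            "L": frozenset({"c1"}),
        },
        root="root",
    )
    return g.with_annotations(
        {
            "c1": {"g1"},
            "L": {"g2"},
            "c2": {f"g{i}" for i in range(3, 9)},
        }
    )


@pytest.fixture
def diamond_dag() -> OntologyGraph:
    """Leaf L under both m1 and m2, both under root; only L annotated."""
    g = OntologyGraph(
        terms=frozenset({"root", "m1", "m2", "L"}),
        parents={
            "root": frozenset(),
            "m1": frozenset({"root"}),
            "m2": frozenset({"root"}),
            "L": frozenset({"m1", "m2"}),
        },
        root="root",
    )
    return g.with_annotations({"L": {"gA"}})


def random_network(
    rng: np.random.Generator,
    n: int,
    edge_p: float = 0.2,
    weighted: bool = False,
    prefix: str = "n",
) -> WeightedNetwork:
    """Random symmetric network, possibly with isolated nodes."""
    nodes = tuple(f"{prefix}{i}" for i in range(n))
    A = (rng.random((n, n)) < edge_p).astype(float)
    if weighted:
        A *= rng.random((n, n)) * 4 + 0.1
    A = np.triu(A, k=1)
    A = A + A.T
    return WeightedNetwork(nodes, A)


def random_hetero_parts(
    rng: np.random.Generator,
    n_enh: int,
    n_dis: int,
    edge_p: float = 0.2,
    assoc_p: float = 0.15,
) -> tuple[WeightedNetwork, WeightedNetwork, BipartiteAssociations]:
    """Random enhancer/disease networks plus a random bipartite layer."""
    W_E = random_network(rng, n_enh, edge_p, weighted=False, prefix="e")
    W_D = random_network(rng, n_dis, edge_p, weighted=True, prefix="d")
    B = (rng.random((n_enh, n_dis)) < assoc_p).astype(float)
    assoc = BipartiteAssociations(W_E.nodes, W_D.nodes, B)
    return W_E, W_D, assoc


def random_dag(
    rng: np.random.Generator, n_terms: int, n_genes: int = 12
) -> OntologyGraph:
    """Random rooted DAG with random sparse annotations (root unannotated)."""
    terms = tuple(f"t{i}" for i in range(n_terms))
    parents: dict[str, frozenset[str]] = {terms[0]: frozenset()}
    for i in range(1, n_terms):
        k = 1 + (rng.random() < 0.3)
        ps = {terms[int(j)] for j in rng.integers(0, i, size=k)}
        parents[terms[i]] = frozenset(ps)
    genes = [f"g{i}" for i in range(n_genes)]
    annot = {}
    for t in terms[1:]:
        k = int(rng.integers(0, 3))
        if k:
            annot[t] = {genes[int(j)] for j in rng.integers(0, n_genes, size=k)}
    if not annot:  # guarantee at least one annotated term
        annot[terms[-1]] = {genes[0]}
    g = OntologyGraph(frozenset(terms), parents, terms[0])
    return g.with_annotations(annot)


def direct_steady_state(
    T: np.ndarray, p0: np.ndarray, gamma: float
) -> np.ndarray:
    """Independent oracle: solve the restart-walk fixed point directly.

    With dangling redirection the iteration is linear,
    p = (1-g)(T + p0 d^T) p + g p0 with d the dangling indicator, so the
    steady state solves (I - (1-g)(T + p0 d^T)) p = g p0.
    """
    n = len(p0)
    d = (np.asarray(T).sum(axis=0) < 1e-15).astype(float)
    A = np.eye(n) - (1.0 - gamma) * (np.asarray(T) + np.outer(p0, d))
    return np.linalg.solve(A, gamma * np.asarray(p0))
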