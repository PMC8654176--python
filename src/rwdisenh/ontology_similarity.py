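"""Information content and Resnik similarity over the annotated disease DAG.

The disease similarity network is built from a gene-annotated ontology:
each term's corpus frequency is

    f(t) = |Annot(t)| + sum over children c of f(c)

(the literal recursion; on multi-parent DAGs a gene reachable through
several children is counted once per path — a ``distinct_genes`` flag
switches to the conventional variant that counts each distinct gene once
over the term's whole descendant set). Information content is
IC(t) = -ln(f(t) / f(root)), and the similarity of two terms is the IC of
their most informative common ancestor (Resnik). Disease pairs with
positive similarity become weighted edges of the disease similarity
network W_D.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from graphlib import TopologicalSorter
from typing import Iterable

from .io_formats import OntologyGraph
from .network import WeightedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "NoAnnotationsError",
    "UndefinedICError",
    "ICTable",
    "compute_counts",
    "information_content",
    "resnik_similarity",
    "build_disease_similarity_network",
]


class NoAnnotationsError(ValueError):
    """The ontology carries no gene annotations anywhere (f(root) = 0)."""


class UndefinedICError(ValueError):
    """IC requested for a term with zero corpus frequency."""


@dataclass(frozen=True)
class ICTable:
    """Corpus counts ``f`` and information content ``ic`` per term.

    ``ic`` is defined only for terms with ``f > 0``; the root always has
    ``ic = 0``.
    """

    f: dict[str, float]
    ic: dict[str, float]
    root: str


def compute_counts(g: OntologyGraph, *, distinct_genes: bool = False) -> ICTable:
    """Evaluate the corpus-frequency recursion and derive IC.

    With ``distinct_genes=False`` (default) the printed recursion is
    evaluated literally by memoized topological order: each term's ``f``
    is computed once and contributes once per parent listing it as a
    child, so genes reachable via multiple children/paths are
    double-counted. With ``distinct_genes=True``, ``f(t)`` is the number
    of distinct genes annotated to ``t`` or any of its descendants.

    Raises :class:`NoAnnotationsError` if no term is annotated.
    """
    order = tuple(
        TopologicalSorter({t: g.children[t] for t in g.terms}).static_order()
    )  # children before parents
    f: dict[str, float] = {}
    if distinct_genes:
        pool: dict[str, set[str]] = {}
        for t in order:
            genes = set(g.annot.get(t, ()))
            for c in g.children[t]:
                genes |= pool[c]
            pool[t] = genes
            f[t] = float(len(genes))
    else:
        for t in order:
            f[t] = float(len(g.annot.get(t, ()))) + sum(
                f[c] for c in g.children[t]
            )
    f_root = f[g.root]
    if f_root == 0:
        raise NoAnnotationsError("ontology has no gene annotations (f(root) = 0)")
    ic = {t: -math.log(ft / f_root) for t, ft in f.items() if ft > 0}
    return ICTable(f, ic, g.root)


def information_content(ict: ICTable, t: str) -> float:
    """IC(t) = -ln(f(t)/f(root)); natural logarithm.

    Raises :class:`UndefinedICError` when ``f(t) = 0``.
    """
    if t not in ict.f:
        raise KeyError(f"unknown term {t!r}")
    if t not in ict.ic:
        raise UndefinedICError(f"term {t!r} has f = 0; IC is undefined")
    return ict.ic[t]


def resnik_similarity(
    ict: ICTable,
    g: OntologyGraph,
    t_i: str,
    t_j: str,
    *,
    reflexive: bool = True,
) -> float:
    """Max IC over the shared ancestors of ``t_i`` and ``t_j``.

    Ancestor sets are reflexive by default (a term counts as its own
    ancestor, so ``sim(t, t) = IC(t)`` and a parent/child pair scores the
    parent's IC). Pairs whose only shared ancestor is the root score 0.
    """
    information_content(ict, t_i)  # validates presence + defined IC
    information_content(ict, t_j)
    shared = g.ancestors(t_i, reflexive=reflexive) & g.ancestors(
        t_j, reflexive=reflexive
    )
    return max((ict.ic[c] for c in shared if c in ict.ic), default=0.0)


def build_disease_similarity_network(
    ict: ICTable,
    g: OntologyGraph,
    terms: Iterable[str],
    *,
    reflexive: bool = True,
) -> WeightedNetwork:
    """Evaluate all unordered term pairs; keep pairs with similarity > 0.

    The node set is the input term set (isolated nodes retained). Terms
    with undefined IC (no annotations anywhere below them) are excluded
    from the network, with a logged count.
    """
    terms = list(dict.fromkeys(terms))
    unknown = [t for t in terms if t not in g.terms]
    if unknown:
        raise KeyError(f"terms not in ontology: {unknown}")
    kept = [t for t in terms if t in ict.ic]
    if len(kept) < len(terms):
        logger.info(
            "excluded %d terms with undefined IC from the similarity network",
            len(terms) - len(kept),
        )
    if len(kept) < 2:
        raise ValueError("need at least 2 terms with defined IC")
    # per-term map: ancestor -> IC, for fast pairwise max over intersections
    anc_ic = {
        t: {
            a: ict.ic[a]
            for a in g.ancestors(t, reflexive=reflexive)
            if a in ict.ic
        }
        for t in kept
    }
    edges = []
    for i, ti in enumerate(kept):
        ai = anc_ic[ti]
        for tj in kept[i + 1 :]:
            aj = anc_ic[tj]
            small, large = (ai, aj) if len(ai) <= len(aj) else (aj, ai)
            sim = max((v for a, v in small.items() if a in large), default=0.0)
            if sim > 0:
                edges.append((ti, tj, sim))
    return WeightedNetwork.from_edges(tuple(kept), edges)
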