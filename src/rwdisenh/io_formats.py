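"""Readers and writers for every external representation the toolkit touches.

Formats
-------
* disease ontology: OBO (via :mod:`obonet`) or a two-column child->parent TSV
* term -> gene annotation corpus: TSV with columns ``term``, ``gene``
* enhancer -> target-gene map: TSV with columns ``enhancer``, ``gene``
* disease-enhancer associations: TSV with columns ``disease``, ``enhancer``
  (optional ``provenance``)
* network edge lists: TSV; rankings: TSV; enhancer intervals: BED

Dialect: tab-separated, UTF-8, ``#``-prefixed comment lines ignored, one
header row. Enhancers are identified by genomic interval strings such as
``chr16:53799602-53801200``, interpreted as 1-based inclusive coordinates;
the interval is an opaque identifier everywhere except BED export, which
converts to 0-based half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet
import pandas as pd

from .network import WeightedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "SchemaError",
    "OntologyStructureError",
    "EnhancerID",
    "parse_enhancer_id",
    "OntologyGraph",
    "read_ontology",
    "TargetMap",
    "read_target_map",
    "AssociationTable",
    "read_associations",
    "read_annotations",
    "write_rankings",
    "write_edge_list",
    "read_edge_list",
    "write_bed",
]


class ParseError(ValueError):
    """Malformed identifier or field value."""


class SchemaError(ValueError):
    """Input table missing required structure."""


class OntologyStructureError(ValueError):
    """Ontology graph violates the DAG/rooted-tree contract."""


# ---------------------------------------------------------------------------
# Enhancer identifiers
# ---------------------------------------------------------------------------

_ENHANCER_RE = re.compile(r"^(?P<chrom>[^:\s]+):(?P<start>\d+)[-–](?P<end>\d+)$")


@dataclass(frozen=True)
class EnhancerID:
    """A genomic interval string naming an enhancer.

    Coordinates are kept exactly as printed (1-based inclusive). The
    interval is never merged or overlapped with others; downstream math
    treats it as an opaque identifier.
    """

    chrom: str
    start: int
    end: int
    raw: str

    def __str__(self) -> str:  # canonical, hyphen-separated
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def bed_fields(self) -> tuple[str, int, int]:
        """0-based half-open BED coordinates."""
        return self.chrom, self.start - 1, self.end


def parse_enhancer_id(raw: str) -> EnhancerID:
    """Parse ``chrom:start-end`` (hyphen or en-dash separator).

    Raises :class:`ParseError` naming the offending token on malformed
    input or when ``start >= end``.
    """
    m = _ENHANCER_RE.match(raw.strip())
    if m is None:
        raise ParseError(f"malformed enhancer identifier: {raw!r}")
    start, end = int(m["start"]), int(m["end"])
    if start >= end:
        raise ParseError(f"enhancer {raw!r}: start {start} >= end {end}")
    return EnhancerID(m["chrom"], start, end, raw.strip())


# ---------------------------------------------------------------------------
# Ontology
# ---------------------------------------------------------------------------


@dataclass
class OntologyGraph:
    """Rooted disease-term DAG with per-term gene annotations.

    ``parents`` maps each term to the set of terms it ``is_a``; the unique
    term with no parents is ``root``. ``annot`` holds the genes *directly*
    annotated to each term (may be empty).
    """

    terms: frozenset[str]
    parents: dict[str, frozenset[str]]
    root: str
    annot: dict[str, frozenset[str]] = field(default_factory=dict)
    _children: dict[str, frozenset[str]] | None = field(
        default=None, repr=False, compare=False
    )
    _anc_cache: dict[str, frozenset[str]] = field(
        default_factory=dict, repr=False, compare=False
    )

    @property
    def children(self) -> dict[str, frozenset[str]]:
        if self._children is None:
            ch: dict[str, set[str]] = {t: set() for t in self.terms}
            for t, ps in self.parents.items():
                for p in ps:
                    ch[p].add(t)
            self._children = {t: frozenset(s) for t, s in ch.items()}
        return self._children

    def ancestors(self, term: str, *, reflexive: bool = True) -> frozenset[str]:
        """All terms reachable via parent links (reflexive by default)."""
        if term not in self.terms:
            raise KeyError(f"unknown term {term!r}")
        if term not in self._anc_cache:
            anc: set[str] = {term}
            stack = list(self.parents.get(term, ()))
            while stack:
                t = stack.pop()
                if t not in anc:
                    anc.add(t)
                    stack.extend(self.parents.get(t, ()))
            self._anc_cache[term] = frozenset(anc)
        out = self._anc_cache[term]
        return out if reflexive else out - {term}

    def with_annotations(
        self, mapping: Mapping[str, Iterable[str]]
    ) -> "OntologyGraph":
        """Return a copy with direct gene annotations attached.

        Annotations for terms absent from the graph are dropped (count
        logged); term structure is unchanged.
        """
        known, dropped = {}, 0
        for t, genes in mapping.items():
            if t in self.terms:
                known[t] = frozenset(genes)
            else:
                dropped += 1
        if dropped:
            logger.info("dropped annotations for %d unknown terms", dropped)
        return replace(self, annot=known, _anc_cache={})


def _validate_ontology(edges: list[tuple[str, str]], terms: set[str]) -> OntologyGraph:
    g = nx.DiGraph()
    g.add_nodes_from(terms)
    g.add_edges_from(edges)  # child -> parent
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise OntologyStructureError(f"ontology contains a cycle: {cycle}")
    roots = sorted(n for n in g.nodes if g.out_degree(n) == 0)
    if len(roots) != 1:
        raise OntologyStructureError(f"ontology must have one root, found: {roots}")
    parents = {t: frozenset(g.successors(t)) for t in g.nodes}
    return OntologyGraph(frozenset(g.nodes), parents, roots[0])


def read_ontology(path: str | Path) -> OntologyGraph:
    """Read an ontology from OBO or a two-column child->parent TSV.

    Only ``is_a`` relations are kept; obsolete terms are dropped. The
    result must be a DAG with a unique root, else
    :class:`OntologyStructureError` is raised (listing one cycle or the
    competing roots).
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        head = fh.read(4096)
    if path.suffix == ".obo" or "format-version:" in head or "[Term]" in head:
        graph = obonet.read_obo(path)  # drops obsolete terms by default
        edges = [
            (child, parent)
            for child, parent, key in graph.edges(keys=True)
            if key == "is_a"
        ]
        terms = set(graph.nodes)
    else:
        df = _read_tsv(path, ("child", "parent"))
        edges = list(df.itertuples(index=False, name=None))
        terms = set(df["child"]) | set(df["parent"])
    if not terms:
        raise SchemaError(f"{path}: no ontology terms found")
    return _validate_ontology(edges, terms)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    for c in df.columns:
        df[c] = df[c].str.strip()
    if df[list(required)].isna().any().any() or (df[list(required)] == "").any().any():
        raise SchemaError(f"{path}: empty value in a required column")
    n_before = len(df)
    df = df.drop_duplicates().reset_index(drop=True)
    if len(df) < n_before:
        logger.info("%s: collapsed %d duplicate rows", path, n_before - len(df))
    logger.info("%s: %d rows", path, len(df))
    return df


@dataclass(frozen=True)
class TargetMap:
    """Mapping enhancer id -> set of target gene symbols."""

    targets: Mapping[str, frozenset[str]]

    def __post_init__(self):
        for e, genes in self.targets.items():
            if not genes:
                raise ValueError(f"enhancer {e!r} has an empty target set")

    @property
    def enhancers(self) -> tuple[str, ...]:
        return tuple(self.targets)

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for g in self.targets.values():
            out |= g
        return frozenset(out)

    @property
    def n_genes(self) -> int:
        """Total number of distinct target genes in the corpus (``n``)."""
        return len(self.genes)


def read_target_map(path: str | Path) -> TargetMap:
    """Read a long-format enhancer->gene TSV (columns ``enhancer``, ``gene``)."""
    df = _read_tsv(path, ("enhancer", "gene"))
    for i, raw in enumerate(df["enhancer"]):
        try:
            parse_enhancer_id(raw)
        except ParseError as exc:
            raise ParseError(f"{path}, row {i + 2}: {exc}") from exc
    grouped = df.groupby("enhancer", sort=True)["gene"].agg(frozenset)
    return TargetMap(dict(grouped))


@dataclass(frozen=True)
class AssociationTable:
    """Known disease-enhancer association pairs (deduplicated)."""

    pairs: tuple[tuple[str, str], ...]  # (disease_id, enhancer_id)

    @property
    def diseases(self) -> tuple[str, ...]:
        seen = dict.fromkeys(d for d, _ in self.pairs)
        return tuple(seen)

    @property
    def enhancers(self) -> tuple[str, ...]:
        seen = dict.fromkeys(e for _, e in self.pairs)
        return tuple(seen)

    def by_disease(self) -> dict[str, tuple[str, ...]]:
        out: dict[str, list[str]] = {}
        for d, e in self.pairs:
            out.setdefault(d, []).append(e)
        return {d: tuple(v) for d, v in out.items()}

    def by_enhancer(self) -> dict[str, tuple[str, ...]]:
        out: dict[str, list[str]] = {}
        for d, e in self.pairs:
            out.setdefault(e, []).append(d)
        return {e: tuple(v) for e, v in out.items()}


def read_associations(path: str | Path) -> AssociationTable:
    """Read a disease-enhancer association TSV (``disease``, ``enhancer``)."""
    df = _read_tsv(path, ("disease", "enhancer"))
    for i, raw in enumerate(df["enhancer"]):
        try:
            parse_enhancer_id(raw)
        except ParseError as exc:
            raise ParseError(f"{path}, row {i + 2}: {exc}") from exc
    pairs = tuple(
        dict.fromkeys(zip(df["disease"].tolist(), df["enhancer"].tolist()))
    )
    return AssociationTable(pairs)


def read_annotations(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a term->gene annotation TSV (columns ``term``, ``gene``)."""
    df = _read_tsv(path, ("term", "gene"))
    grouped = df.groupby("term", sort=True)["gene"].agg(frozenset)
    return dict(grouped)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_rankings(result, path: str | Path) -> None:
    """Write a :class:`~rwdisenh.diffusion_ranking.RankingResult` as TSV.

    Columns ``node_id``, ``score``, ``rank``; sorted by rank then node id.
    """
    if not result.candidates:
        raise ValueError("cannot write an empty ranking")
    rows = sorted(
        ((n, result.scores[n], result.ranks[n]) for n in result.candidates),
        key=lambda r: (r[2], r[0]),
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_id\tscore\trank\n")
        for n, s, r in rows:
            fh.write(f"{n}\t{s!r}\t{r:g}\n")


def write_edge_list(network: WeightedNetwork, path: str | Path) -> None:
    """Write a weighted edge list TSV; isolated nodes get a single-column row."""
    connected: set[str] = set()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source\ttarget\tweight\n")
        for u, v, w in network.edges():
            fh.write(f"{u}\t{v}\t{w!r}\n")
            connected.update((u, v))
        for n in network.nodes:
            if n not in connected:
                fh.write(f"{n}\t\t\n")


def read_edge_list(path: str | Path) -> WeightedNetwork:
    """Inverse of :func:`write_edge_list` (node and edge sets round-trip)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        dtype={"source": str, "target": str},
        float_precision="round_trip",
    )
    for col in ("source", "target", "weight"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column(s) ['{col}']")
    nodes: dict[str, None] = {}
    edges = []
    for _, row in df.iterrows():
        nodes.setdefault(row["source"])
        if isinstance(row["target"], str) and row["target"]:
            nodes.setdefault(row["target"])
            edges.append((row["source"], row["target"], float(row["weight"])))
    return WeightedNetwork.from_edges(tuple(nodes), edges)


def write_bed(ids: Iterable[EnhancerID], path: str | Path) -> None:
    """Export enhancer intervals as BED3 (0-based half-open)."""
    ids = list(ids)
    if not ids:
        raise ValueError("cannot write an empty BED file")
    with open(path, "w", encoding="utf-8") as fh:
        for eid in ids:
            chrom, start, end = eid.bed_fields
            fh.write(f"{chrom}\t{start}\t{end}\n")
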