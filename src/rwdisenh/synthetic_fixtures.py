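"""Seeded generators for every input the toolkit consumes.

Real runs read a disease ontology, a term->gene annotation corpus, an
enhancer->target-gene map, and a known disease-enhancer association
table. This module fabricates all four with a *plantable* association
signal so end-to-end prioritization is testable without any download.

Signal model
------------
Diseases are partitioned into groups; each group owns a branch of the
generated ontology and a dedicated pool of target genes, and a subset of
enhancers. With signal strength ``s`` in [0, 1]:

* a disease's ontology term falls inside its group's branch with
  probability ``s`` (making co-grouped diseases ontologically close,
  hence similar in the Resnik sense), else anywhere;
* an enhancer belonging to a group draws each target gene from the
  group's pool with probability ``s`` (making co-grouped enhancers share
  targets, hence hypergeometrically linked), else uniformly;
* each of a disease's known enhancers is drawn from its group's enhancer
  subset with probability ``s``, else from all enhancers.

At ``s = 0`` groups are invisible: associations, targets, and term
placement are fully random, so downstream LOOCV AUC sits at chance. Each
generation stage uses its own RNG stream derived from the master seed by
a fixed offset, so adding a stage never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import AssociationTable, OntologyGraph, TargetMap

__all__ = [
    "FixtureSpec",
    "Fixture",
    "generate_ontology",
    "generate_hetero_fixture",
    "shuffled_associations",
    "write_fixture",
]

# one RNG stream per generation stage (fixed offsets from the master seed)
_STAGE_STRUCTURE = 0
_STAGE_DISEASES = 1
_STAGE_ANNOTATIONS = 2
_STAGE_TARGETS = 3
_STAGE_ASSOCIATIONS = 4


@dataclass(frozen=True)
class FixtureSpec:
    """Shape and signal of one synthetic input set.

    Defaults (30 diseases / 120 enhancers / 300 genes / 60 ontology
    terms) are large enough for stable LOOCV AUCs yet run in seconds.
    """

    seed: int = 0
    n_terms: int = 60
    dag_branching: int = 3
    n_genes: int = 300
    n_enhancers: int = 120
    targets_per_enhancer: int = 4
    n_diseases: int = 30
    assoc_per_disease: int = 4
    signal_strength: float = 0.9

    def __post_init__(self) -> None:
        if self.n_terms < 3:
            raise ValueError("need at least 3 ontology terms")
        if self.n_enhancers < 2:
            raise ValueError("need at least 2 enhancers")
        if self.n_diseases < 1:
            raise ValueError("need at least 1 disease")
        if not (0 <= self.signal_strength <= 1):
            raise ValueError("signal_strength must lie in [0, 1]")
        if self.dag_branching < 1 or self.targets_per_enhancer < 1:
            raise ValueError("branching and targets per enhancer must be >= 1")
        if self.n_diseases > self.n_terms - 1:
            raise ValueError("more diseases than non-root ontology terms")
        if self.assoc_per_disease > self.n_enhancers:
            raise ValueError("assoc_per_disease exceeds the enhancer count")

    @property
    def n_groups(self) -> int:
        return max(2, min(6, self.n_diseases, self.n_terms - 1))

    def _rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng((int(self.seed), stage))


@dataclass(frozen=True)
class Fixture:
    """One complete synthetic input set (plus generator-side truth)."""

    spec: FixtureSpec
    ontology: OntologyGraph  # annotations attached
    target_map: TargetMap
    associations: AssociationTable
    disease_terms: tuple[str, ...]
    group_of_disease: dict[str, int] = field(compare=False)
    group_of_enhancer: dict[str, int] = field(compare=False)  # -1 = background


def _build_structure(
    spec: FixtureSpec,
) -> tuple[dict[str, frozenset[str]], dict[str, int], str, tuple[str, ...]]:
    """Random rooted DAG: root, one branch head per group, random tree
    growth within branches plus occasional same-branch cross-links."""
    rng = spec._rng(_STAGE_STRUCTURE)
    terms = tuple(f"T{i:03d}" for i in range(spec.n_terms))
    root = terms[0]
    g = spec.n_groups
    parents: dict[str, set[str]] = {root: set()}
    branch_of: dict[str, int] = {root: -1}
    branch_members: list[list[str]] = [[] for _ in range(g)]
    for b in range(g):
        head = terms[1 + b]
        parents[head] = {root}
        branch_of[head] = b
        branch_members[b].append(head)
    children_count = {t: 0 for t in terms}
    for t in terms[1 + g :]:
        b = int(rng.integers(g))
        members = branch_members[b]
        open_slots = [m for m in members if children_count[m] < spec.dag_branching]
        cands = open_slots or members
        parent = cands[int(rng.integers(len(cands)))]
        parents[t] = {parent}
        children_count[parent] += 1
        # occasional second parent from the same branch keeps the graph a DAG
        if len(members) > 1 and rng.random() < 0.1:
            other = members[int(rng.integers(len(members)))]
            if other != parent:
                parents[t].add(other)
        branch_of[t] = b
        members.append(t)
    return (
        {t: frozenset(ps) for t, ps in parents.items()},
        branch_of,
        root,
        terms,
    )


def _place_diseases(
    spec: FixtureSpec,
    terms: tuple[str, ...],
    branch_of: dict[str, int],
    root: str,
) -> tuple[tuple[str, ...], dict[str, int]]:
    rng = spec._rng(_STAGE_DISEASES)
    s = spec.signal_strength
    g = spec.n_groups
    by_branch: dict[int, list[str]] = {b: [] for b in range(g)}
    for t in terms:
        if t != root:
            by_branch[branch_of[t]].append(t)
    used: set[str] = set()
    disease_terms: list[str] = []
    group_of: dict[str, int] = {}
    for i in range(spec.n_diseases):
        grp = i % g
        b = grp if rng.random() < s else int(rng.integers(g))
        free = [t for t in by_branch[b] if t not in used]
        if not free:
            free = [t for t in terms if t != root and t not in used]
        term = free[int(rng.integers(len(free)))]
        used.add(term)
        disease_terms.append(term)
        group_of[term] = grp
    return tuple(disease_terms), group_of


def _annotate(
    spec: FixtureSpec,
    terms: tuple[str, ...],
    root: str,
    disease_terms: tuple[str, ...],
    genes: tuple[str, ...],
) -> dict[str, frozenset[str]]:
    rng = spec._rng(_STAGE_ANNOTATIONS)
    annot: dict[str, set[str]] = {}
    for t in terms:
        if t == root:
            continue
        k = int(rng.integers(0, 3))
        if k:
            annot[t] = {genes[int(j)] for j in rng.integers(len(genes), size=k)}
    for t in disease_terms:  # disease terms must carry annotation (defined IC)
        if not annot.get(t):
            annot[t] = {genes[int(rng.integers(len(genes)))]}
    return {t: frozenset(gs) for t, gs in annot.items()}


def _make_enhancer_ids(spec: FixtureSpec, rng: np.random.Generator) -> tuple[str, ...]:
    ids: dict[str, None] = {}
    while len(ids) < spec.n_enhancers:
        chrom = f"chr{int(rng.integers(1, 23))}"
        start = int(rng.integers(100_000, 100_000_000))
        end = start + int(rng.integers(200, 5000))
        ids.setdefault(f"{chrom}:{start}-{end}")
    return tuple(ids)


def generate_ontology(spec: FixtureSpec) -> OntologyGraph:
    """Rooted random DAG with gene annotations; identical for equal specs."""
    parents, branch_of, root, terms = _build_structure(spec)
    disease_terms, _ = _place_diseases(spec, terms, branch_of, root)
    genes = tuple(f"G{i:04d}" for i in range(spec.n_genes))
    annot = _annotate(spec, terms, root, disease_terms, genes)
    g = OntologyGraph(frozenset(terms), parents, root)
    return g.with_annotations(annot)


def generate_hetero_fixture(spec: FixtureSpec) -> Fixture:
    """Generate all four inputs with the planted association signal."""
    parents, branch_of, root, terms = _build_structure(spec)
    disease_terms, group_of_disease = _place_diseases(spec, terms, branch_of, root)
    genes = tuple(f"G{i:04d}" for i in range(spec.n_genes))
    annot = _annotate(spec, terms, root, disease_terms, genes)
    ontology = OntologyGraph(frozenset(terms), parents, root).with_annotations(annot)

    s = spec.signal_strength
    g = spec.n_groups
    pool_size = max(5, spec.n_genes // (2 * g))
    pools = [
        genes[b * pool_size : (b + 1) * pool_size] or genes for b in range(g)
    ]

    rng_t = spec._rng(_STAGE_TARGETS)
    enhancer_ids = _make_enhancer_ids(spec, rng_t)
    n_grouped = int(round(0.75 * spec.n_enhancers))
    group_of_enhancer = {
        e: (i % g if i < n_grouped else -1) for i, e in enumerate(enhancer_ids)
    }
    group_enhancers = [
        [e for e in enhancer_ids if group_of_enhancer[e] == b] for b in range(g)
    ]
    targets: dict[str, frozenset[str]] = {}
    for e in enhancer_ids:
        grp = group_of_enhancer[e]
        chosen: set[str] = set()
        for _ in range(spec.targets_per_enhancer):
            if grp >= 0 and rng_t.random() < s:
                pool = pools[grp]
                chosen.add(pool[int(rng_t.integers(len(pool)))])
            else:
                chosen.add(genes[int(rng_t.integers(len(genes)))])
        targets[e] = frozenset(chosen)
    target_map = TargetMap(targets)

    rng_a = spec._rng(_STAGE_ASSOCIATIONS)
    pairs: list[tuple[str, str]] = []
    for d in disease_terms:
        grp = group_of_disease[d]
        picked: set[str] = set()
        guard = 0
        while len(picked) < spec.assoc_per_disease and guard < 1000:
            guard += 1
            if rng_a.random() < s and group_enhancers[grp]:
                cands = group_enhancers[grp]
            else:
                cands = list(enhancer_ids)
            picked.add(cands[int(rng_a.integers(len(cands)))])
        for e in sorted(picked):
            pairs.append((d, e))
    associations = AssociationTable(tuple(pairs))
    return Fixture(
        spec,
        ontology,
        target_map,
        associations,
        disease_terms,
        group_of_disease,
        group_of_enhancer,
    )


def shuffled_associations(
    assoc: AssociationTable, rng: np.random.Generator
) -> AssociationTable:
    """Permute the enhancer column — the null with association structure
    destroyed but both margins preserved (up to duplicate collapse)."""
    diseases = [d for d, _ in assoc.pairs]
    enhancers = [e for _, e in assoc.pairs]
    pairs: tuple[tuple[str, str], ...] = ()
    for _ in range(200):  # re-draw until the permutation collides nowhere
        perm = rng.permutation(len(enhancers))
        cand = [(d, enhancers[int(k)]) for d, k in zip(diseases, perm)]
        if len(set(cand)) == len(cand):
            pairs = tuple(cand)
            break
    else:
        pairs = tuple(dict.fromkeys(cand))
    return AssociationTable(pairs)


# ---------------------------------------------------------------------------
# File output (exactly the dialects io_formats reads)
# ---------------------------------------------------------------------------


def write_fixture(fix: Fixture, outdir: str | Path) -> dict[str, Path]:
    """Write ontology.obo, annotations.tsv, targets.tsv, associations.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ontology": outdir / "ontology.obo",
        "annotations": outdir / "annotations.tsv",
        "targets": outdir / "targets.tsv",
        "associations": outdir / "associations.tsv",
    }
    g = fix.ontology
    with open(paths["ontology"], "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        for t in sorted(g.terms):
            fh.write(f"\n[Term]\nid: {t}\nname: {t}\n")
            for p in sorted(g.parents[t]):
                fh.write(f"is_a: {p} ! {p}\n")
    with open(paths["annotations"], "w", encoding="utf-8") as fh:
        fh.write("term\tgene\n")
        for t in sorted(g.annot):
            for gene in sorted(g.annot[t]):
                fh.write(f"{t}\t{gene}\n")
    with open(paths["targets"], "w", encoding="utf-8") as fh:
        fh.write("enhancer\tgene\n")
        for e in fix.target_map.enhancers:
            for gene in sorted(fix.target_map.targets[e]):
                fh.write(f"{e}\t{gene}\n")
    with open(paths["associations"], "w", encoding="utf-8") as fh:
        fh.write("disease\tenhancer\n")
        for d, e in fix.associations.pairs:
            fh.write(f"{d}\t{e}\n")
    return paths
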