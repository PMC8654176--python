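# Methods

## Problem setting

Given a disease ontology (a rooted DAG of disease terms), a term→gene
annotation corpus, an enhancer→target-gene table, and a set of curated
disease–enhancer associations, the toolkit scores how strongly each
candidate enhancer is associated with a disease of interest (and
symmetrically, candidate diseases for an enhancer). The guiding
assumption is guilt by association on two complementary axes: enhancers
sharing target genes tend to share diseases, and similar diseases tend
to share enhancers.

## Disease similarity network

Each term's corpus frequency is computed by the recursion
`f(t) = |Annot(t)| + Σ_{c∈Children(t)} f(c)`, evaluated in memoized
topological order so each term's `f` is computed once. On a multi-parent
DAG this literal recursion counts a gene once per path from an annotated
descendant, which overstates frequencies near the root relative to the
conventional definition. The literal recursion is the default because it
is the published form of the model this package implements;
`compute_counts(..., distinct_genes=True)` switches to the conventional
variant (`f(t)` = number of distinct genes annotated to `t` or any
descendant) for comparison. Information content is
`IC(t) = -ln(f(t)/f(root))`; the natural logarithm is fixed so tests are
exact (any base only rescales all similarities by a constant).

Resnik similarity is the maximum IC over the shared ancestors of two
terms. Ancestor sets are reflexive by default — a term is its own
ancestor, so `sim(t, t) = IC(t)` and a parent/child pair scores the
parent's IC — which is the standard Resnik convention; a
`reflexive=False` flag gives the proper-ancestor variant. Terms with
`f = 0` have undefined IC and are excluded from the similarity network
(with a logged count) rather than assigned infinite IC; this mirrors
restricting the analysis to annotated terms. Pairs with similarity
exactly 0 (only the root in common) are not stored as edges; isolated
nodes are retained.

## Enhancer functional interaction network

For every unordered enhancer pair the upper-tail hypergeometric
probability of observing at least `k` shared target genes is computed,
with `n` the number of distinct genes in the supplied target map (always
computed from the input, never assumed). Pairs with `p ≤ α` (default
0.05) become unweighted edges; `p`-values are retained only as edge
metadata and in the audit output. No multiple-testing correction is
applied — the published construction thresholds raw `p`, and the audit
table lets users apply FDR control downstream if desired. The tail
probability is delegated to `scipy.stats.hypergeom.sf`, which evaluates
in log-space; an exhaustive-enumeration oracle in the test suite
verifies agreement to 1e-12 for every configuration with `n ≤ 12`.

## Heterogeneous network assembly

Enhancers are indexed first, diseases second. Rows of each block are
out-probabilities. A node with both intra-network edges and bipartite
links splits its outgoing mass `1-λ` intra / `λ` inter, after
row-normalizing each block. A node with links of only one kind gives
that kind its full unit of mass: without this, an enhancer with disease
links but no functional-interaction edges would emit total mass `λ < 1`
and the operator would leak probability. This renormalization is the
standard heterogeneous random-walk construction and is required by the
package's stochasticity contract (outgoing mass `1 ± 1e-12` for every
connected node, audited over random fixtures in the tests).

The recurrence `P^{t+1} = (1-γ) W' P^t + γ P^0` conserves mass only if
the operator applied to the column vector `P` is column-stochastic, so
the stored operator is the transpose of the row-normalized assembly.
Dangling nodes (no links at all) keep zero rows; at walk time the mass
that flows into them is redirected to the seed vector `P^0`, which keeps
the iteration stochastic without altering any defined transition row.

Seed vectors: the homogeneous form puts `1/|S|` on each source node.
The heterogeneous form puts `η` on the disease of interest and
`(1-η)/|S'|` on each known enhancer. When `S'` is empty the definition
is degenerate; the package places the full unit of mass on the disease
(with a logged warning). This rule is what lets the heterogeneous LOOCV
cover diseases with exactly one known enhancer.

## Ranking engines

* **Restart walk (primary engine).** Power iteration with L1 residual
  tolerance 1e-10 and a 1000-iteration cap; non-convergence raises an
  error carrying the last residual. The spectral radius of the update is
  at most `1-γ`, so convergence is geometric and the tolerance is
  reached in a few dozen iterations at the default `γ = 0.5`. The
  returned vector sums to 1 within 1e-9. An independent oracle — the
  direct linear solve of `(I - (1-γ)(T + P^0 d^T)) P = γ P^0`, with `d`
  the dangling indicator — verifies the iterative solution to 1e-8 on
  random homogeneous and heterogeneous fixtures.
* **PageRank with Priors.** Same restart recurrence driven by the
  out-degree-normalized adjacency with back-probability `β`
  (default 0.7). On undirected networks each edge counts as two directed
  links, so the out-degree normalization coincides with the row
  normalization of the restart walk and the two engines agree on
  symmetric inputs; the test suite checks this identity numerically. On
  the heterogeneous view the assembled operator replaces the adjacency.
* **MaxLink.** Candidates are direct neighbors of the source set,
  scored by their link count `ML(v)` to it. Candidates whose link count
  is unsurprising given their degree — hypergeometric point probability
  `C(|S|,ML) C(|V|-|S|, deg(v)-ML) / C(|V|, deg(v)) ≥ 0.5` — are
  discarded. The point (single-term) probability is the default because
  it is the published form; `tail=True` switches to the canonical
  upper-tail `P(X ≥ ML)`. For evaluation, candidates left unranked
  (non-neighbors or filtered) are placed below all ranked candidates,
  tied — the least-information completion that yields the total order
  LOOCV needs.

Ties in any engine's scores receive average ranks (the unbiased
convention for AUC).

## Evaluation protocol

LOOCV runs per entity. Disease-centric heterogeneous view: every disease
with at least one known in-network enhancer is eligible (single-enhancer
diseases use the degenerate disease-only seed). Homogeneous views
require at least two known associations, since one must seed while
another is held out; ineligible entities are skipped with a logged
reason. For each trial the held-out node is ranked against all nodes not
known to be associated with the entity — the entity's other known
associations are neither positives nor negatives and are excluded from
the candidate set. In the heterogeneous view the held-out association is
also removed from the bipartite layer for that trial, so the link being
predicted never informs the prediction.

One ROC curve is built per entity from all its trials by sweeping a rank
threshold: true/false positive and negative counts at each threshold
give sensitivity and 1−specificity, and the AUC is the trapezoidal
integral. Thresholds visit every distinct pooled rank value: on
tie-free integer ranks this is identical to sweeping τ = 1..|C∪{s}|,
and with tie-averaged fractional ranks it is the exact empirical curve,
making the AUC equal the tie-adjusted Mann–Whitney statistic to machine
precision (verified against a brute-force pairwise oracle). Per-entity
AUCs are aggregated as mean ± SE; Welch's unequal-variance t-test
(delegated to scipy) compares configurations. The parameter sweep varies
one of `γ`, `η`, `λ` over {0.1, 0.3, 0.5, 0.7, 0.9} with the other two
at 0.5 — fifteen grid points.

Default parameters are `λ = η = γ = 0.5`, `β = 0.7`, `α = 0.05`.

## Synthetic data

The generator fabricates all four inputs with a planted association
signal controlled by `signal_strength s ∈ [0, 1]`. Diseases are
partitioned into up to six groups; each group owns one branch of the
generated ontology, a dedicated pool of target genes, and a subset of
enhancers (75% of enhancers belong to a group, the rest are background).
With probability `s`: a disease's term is placed in its group's branch,
an enhancer's target genes come from the group pool, and a disease's
associated enhancers come from the group subset. At `s = 0` all three
choices are uniform and the LOOCV AUC sits at chance. Each generation
stage draws from its own RNG stream derived from the master seed by a
fixed offset, so adding a stage never perturbs earlier ones; equal specs
produce byte-identical files.

Default shape: 30 diseases, 120 enhancers, 300 genes, 60 ontology terms,
4 target genes per enhancer, 4 associations per disease. The small
target sets reflect curated enhancer–target corpora, where most
enhancers have a handful of annotated targets, and they keep the
functional-interaction network sparse enough that a substantial share of
the recoverable signal flows through the disease similarity layer — the
regime the heterogeneous method exists for. Under these conditions the
heterogeneous walk clearly outperforms both the enhancer-only walk and
a shuffled-association null (mean AUCs ≈ 0.81 vs ≈ 0.66 vs ≈ 0.57 over
20 replicates, as recomputed by `scripts/acceptance.py`).

What the fixtures do **not** emulate: the empirical topology of a real
disease ontology (depth, fan-out, term co-annotation structure), the
scale of real corpora (hundreds of diseases, thousands of enhancers),
genomic coordinate realism beyond well-formed interval strings, and
annotation noise such as mis-mapped disease names. Passing the planted
-signal tests therefore demonstrates that the pipeline recovers the kind
of structure it models, not a performance forecast for real data.

A note on the shuffled null: permuting the enhancer column of the
association table preserves both margins, so multiply-associated, highly
connected enhancers remain over-represented among held-out nodes; the
null therefore sits slightly above 0.5 (≈ 0.57) on signalled fixtures.
On signal-free fixtures the mean AUC is within 0.5 ± 0.05.

## Numerical and design choices

* Enhancer interval strings are 1-based inclusive and treated as opaque
  identifiers everywhere; only BED export converts (start−1, end). No
  interval overlap or merging is performed.
* OBO parsing keeps `is_a` relations only; obsolete terms are dropped;
  cycles and multiple roots are structural errors reported with the
  offending cycle/roots.
* TSV dialect: tab-separated, UTF-8, `#` comments ignored, one header
  row; duplicate rows collapse with a logged count.
* Edge-list round trips read floats with `round_trip` precision so
  written networks reload bit-exactly.
* All build/rank/evaluate stages are deterministic given inputs; the
  only randomness in the package is the fixture generator's seeded RNG.

## Known limitations

* Dense matrix algebra: fine to a few thousand nodes per layer; corpora
  beyond ~10^4 enhancers would want a sparse operator.
* One term per disease: term-set (best-match-average) similarity and
  other semantic measures (Lin, Jiang–Conrath, Wang) are out of scope.
* The enhancer network is binarized at `α`; edge-strength weighting and
  FDR-based thresholds are left to downstream users via the audit table.
* MaxLink on the heterogeneous view reduces to its enhancer-network
  behavior under the LOOCV protocol, because candidates are never linked
  to the query disease once the held-out association is removed; only
  the degree/population terms of its filter change.
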