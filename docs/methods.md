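# Methods

## Model and procedure

The pipeline treats a disease as a set of susceptibility genes and a
cell's interaction structure as an undirected simple graph over gene
identifiers.  Identifiers are opaque, case-sensitive strings: mapping
probe sets or protein accessions into one namespace is the caller's
job, because no automatic symbol normalization is reliable across the
mixed sources such data come from.

**Random walk with restart.**  For panel expansion the walker follows
`p_{t+1} = (1−γ) W p_t + γ p_0`, with `W` the column-normalized
adjacency matrix and `p_0` equal mass on the seeds.  For γ ∈ (0, 1] the
map is a contraction with factor 1−γ, so the iteration converges
geometrically to the unique fixed point `p = γ (I − (1−γ) W)⁻¹ p_0`;
the implementation iterates (sparse matrix–vector products) and stops
when the L1 change drops below 1e-10, capped at 10⁵ iterations — at the
default γ = 0.75 this means a few dozen steps.  Isolated nodes cannot
carry walk mass; networks are reduced to their non-isolated part before
propagation and seed sets containing isolated genes are rejected rather
than patched with a teleportation rule.  Ranking ties are broken by
lexicographic gene id so the selection is deterministic.  Seeds retain
restart mass and are counted inside the top-k selection, but not forced
into it; a seed falling outside the cut is logged.

**Overlap significance.**  The observed intersection of the panels is
compared with the intersections of randomly redrawn panels of the same
sizes, drawn uniformly without replacement (and independently of one
another) from the network's gene universe.  The empirical p-value uses
the add-one rule `(n_at_least + 1)/(R + 1)`, which cannot reach zero
and matches standard permutation practice.  Because the empirical
estimate is floored at 1/(R+1), a parametric companion is reported: a
Poisson distribution fitted (by its mean) to the null intersection
counts, with the upper tail evaluated at the observed value.  Rare
k-way overlaps of sparse random sets are closely Poisson, but the
family choice is a modeling decision of this package; both p-values are
always written, labelled with the family.

**CFNN.**  The common-gene first-neighbor network is the *induced*
subgraph on the common genes plus all their direct neighbors — edges
between two neighbors are kept.  The alternative (a star-like union of
edges incident to common genes) discards exactly the triangle structure
that the later module-density comparison measures.

**Enrichment.**  Each pathway is tested two-sided under
`Hypergeometric(N, m, n)`: the p-value doubles the smaller of the two
tails and caps at 1, a transparent convention testable against
exhaustive enumeration.  Pathways with zero overlap are still tested
(they can be significantly depleted).  The default universe is the set
of genes annotated to at least one pathway in the database; all genes
of the network, or a custom list, are available where a different
reference makes sense.  BH runs across all tested pathways;
significance means adjusted p below alpha (default 0.05).

**Pathway clustering and common modules.**  *Associated genes* are the
genes lying in both the CFNN and at least one significant pathway.  The
binary gene × pathway membership matrix over them yields pairwise
pathway distances 1 − cosine (raw 0/1 vectors, no weighting or
centering), and agglomerative clustering cut at a fixed height
partitions the pathways.  For each cluster, intersecting the member
pathways' associated-gene sets and inducing that intersection on the
CFNN gives the common module; clusters whose members share no
associated gene yield an empty module, reported as "None".  Average
linkage is the default.  On the 1 − cosine scale all merge heights lie
in [0, 1], so the cut defaults to 0.7 (within-cluster cosine
similarity roughly ≥ 0.3); cutting near 0.9 would merge pathway columns
that are nearly orthogonal, letting any weakly overlapping pathway
absorb into an otherwise tight cluster and annihilate the gene
intersection.  A cut of 1.1 is meaningful only for linkages whose
heights can exceed 1 and is honored verbatim with `linkage: ward`.

**Clustering coefficient.**  Per node, the fraction of neighbor pairs
that are themselves connected; nodes of degree < 2 contribute 0 (the
dominant convention, which keeps the graph average defined on every
non-empty graph).  Module density is compared with CFNN density as a
direction, not a fixed value.

**Differential expression and components.**  Inputs are assumed
normalized, log-scale values; array preprocessing is out of scope.
The per-gene engine is a Welch two-sample t-test — the contract is "a
two-group test plus BH", with the engine documented and swappable;
duplicate gene rows are mean-averaged at load time (the probe-set
rule).  Genes with zero variance in both groups are marked untestable
and excluded from the BH denominator rather than assigned p = 1, so the
correction is not diluted.  A pathway-diagram component (one or more
interchangeable proteins, e.g. the three α-catenin genes behind one
node) is differentially expressed when any member gene is.  The
observed count of hit components is referred to redraws of equally many
genes from a configurable universe (default: the genes present in the
expression data); p-values follow the same add-one plus Poisson-fit
convention as the overlap test.

## Synthetic study conditions

The generator emulates the real inputs' statistical shape at roughly
one-tenth scale; its defaults are the study conditions for every
end-to-end test: 1500 genes in a preferential-attachment network
(3 edges per new node), panels of 100/60/90 genes sharing exactly 10
planted common genes, 120 pathways of 15–80 genes of which 8 are
enriched, a planted 6-gene clique module, expression with 10 samples
per group, 50 planted differential genes with a +2.0 log-unit shift on
noise sd 1.0.

Planting details, chosen once:

* the module genes are wired into a clique and one planted common gene
  is placed inside the module, so the module is guaranteed to sit in
  the CFNN — without that anchor, module recovery would hinge on a
  random adjacency;
* panel fillers are redrawn until the three-way intersection equals the
  planted set exactly, making overlap recovery a sharp test;
* enriched pathways contain every module gene and draw ~60 % of their
  members from the planted common genes' neighborhood, split evenly
  between the first- and second-neighbor shells.  The 1-hop half puts
  enrichment signal inside the CFNN; the 2-hop half keeps any single
  neighbor gene unlikely to recur in *all* enriched pathways, which
  would otherwise contaminate the module intersection (a 1-hop-only
  pool is small enough for large pathways to absorb it entirely);
* planted differential genes are biased (70 %) toward the enriched
  pathways' gene union, so the expression arm has pathway-level signal
  to find;
* every draw is integer-indexed from seeded generators, so output is
  bit-identical across runs and platforms.

What the generator does **not** emulate: probe-level microarray noise,
inter-database identifier conflicts, correlated gene expression,
degree-dependent annotation bias, and pathway overlap structure of real
KEGG maps.  Passing recovery tests therefore demonstrates the
pipeline's correctness and calibration on networks and gene sets with
realistic degree heterogeneity and planted signal — not performance on
real disease data.

## Numerical choices and degenerate inputs

* RWR: L1 tolerance 1e-10, max 10⁵ iterations; non-convergence is an
  error that reports the last residual.
* Permutation tests: a single integer seed per run drives all draws;
  results embed the seed and are bit-reproducible.
* Hypergeometric tails come from scipy's survival/cumulative functions;
  two-sided doubling is capped at 1.  Direction ties (k exactly at
  expectation) count as enriched.
* Cosine distances are clipped at 0 to absorb floating-point negatives;
  cluster ids are assigned by each cluster's lexicographically smallest
  pathway so numbering is input-order invariant.
* Empty panel intersection warns and halts the pipeline with a clear
  message; empty association matrices, universes or component sets are
  errors rather than silent empties.
* Readers reject structurally ambiguous input (wrong column counts,
  duplicate GMT names, unknown design labels) with the offending line.

## Scale of the shipped experiments

The default synthetic conditions run the full pipeline in a few
seconds.  Null-calibration experiments use 200 pipeline-independent
runs at 499 permutation replicates each, sized so the discrete add-one
p-value has enough resolution for its nominal-level behavior to be
measurable (a three-way overlap null with mean ≈ 8 and a component-hit
null with standard deviation ≈ 3); oracle-equivalence checks enumerate
all hypergeometric parameter combinations with N ≤ 20 and 20 random
graphs of up to 100 nodes for the linear-solve comparison.

## Known limitations

* The Poisson companion p-value is a modeling convenience; heavy
  ties/discreteness aside, the empirical p is the primary statistic.
* Average-linkage cosine clustering has no uncertainty quantification;
  cluster counts are sensitive to the cut height, which is exposed in
  config rather than hidden.
* The Welch engine ignores gene–gene correlation and does not moderate
  variances; with very few samples a moderated engine would be more
  powerful.
* Multi-protein components are hit-or-miss sets; partial concordance
  (some members up, some down) is not modeled.
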