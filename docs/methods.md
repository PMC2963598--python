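# Methods

## Problem definition

Given a profile network `G = (V, E, p)` — an undirected gene interaction
graph whose nodes carry log fold-change expression profiles over `m`
shared conditions — and a constraint triple `(γ, ε, d_min)`, a gene set
`S` of size `k ≥ 2` is a *densely connected bicluster* (DCB) when its
induced subgraph is connected, contains at least `γ·C(k,2)` edges, and all
members are within `ε` of each other in at least `d_min` conditions. The
per-condition spread criterion (max − min ≤ ε) is equivalent to the
all-pairs formulation but costs `O(k)` per condition. A condition counts
toward the subspace only if every member has a non-missing value there —
the conservative treatment of missing data; the stored subspace is the
*maximal* witness (every qualifying condition), not an arbitrary
`d_min`-subset. The target of the search is the set of **maximal** DCBs,
i.e. those not properly contained (as gene sets) in another DCB.

## Enumeration

The lattice of connected subnetworks (child = parent plus one connected
gene) is traversed breadth-first. Level 2 is seeded by every edge whose
endpoint pair is co-expressed in ≥ `d_min` conditions; level `k+1`
candidates are one-neighbor extensions of level-`k` DCBs, deduplicated by
gene set. Completeness for `γ ≥ 0.5` follows from loose anti-monotonicity:
any DCB of size `k+1` contains a size-`k` DCB (remove the
minimum-degree vertex; if that disconnects the graph, vertices of the
smaller component can be removed farthest-first without violating the
density bound when `γ ≥ 0.5`). For `γ < 0.5` the lattice search refuses to
run and the brute-force enumerator (every subset, capped at 18 genes)
serves instead; the two must agree exactly for `γ ≥ 0.5`, which the test
battery checks on hundreds of random instances.

Maximality is decided by a global post-hoc strict-subset pass over all
enumerated DCBs rather than by "has no DCB child": a DCB two sizes larger
need not contain an intermediate DCB through a given set, so the child
test alone could mislabel sets as maximal. Because containment chains end
at maximal sets, checking candidates against the maximal ones only is
sufficient. Output order is canonical (size descending, then
lexicographic gene list), making results independent of input order.

Edge pruning before the search removes every edge whose endpoint pair
fails the pairwise co-expression constraint. The subspace is anti-monotone
under gene-set growth, so such an edge cannot occur inside any DCB and the
maximal-DCB set is unchanged — verified against the brute-force oracle.

## Merging

Incomplete interaction data splits core-attachment modules into
overlapping fragments. Pairs of modules overlapping in at least
`member_overlap` of their members **and** `subspace_overlap` of their
subspaces (intersection over the smaller set; Jaccard optional) are merged
— gene union, subspace intersection — repeatedly until a fixpoint. The
highest-member-overlap pair is merged first, ties broken lexicographically,
which makes the fixpoint deterministic and input-order independent.
Merging deliberately relaxes the constraints: a merged module may fall
below `γ` or below `d_min` co-expressed conditions (logged when it does).
The subspace intersection is chosen over the union because a union could
contain conditions in which no pair of members is co-expressed. Both
thresholds default to 0.75 — large enough that only near-duplicates merge,
small enough to heal one-gene fragmentation — and are mandatory,
explicitly-set knobs in pipeline configuration.

## Ranking and filtering

Two independent upper-tail significance criteria per module (more
co-expressed conditions / more edges = more significant):

* **Co-expression.** For each module size `k`, 2000 connected induced
  subnetworks of size `k` are sampled (uniform start node in components of
  size ≥ k, then repeated uniform neighbor additions) and their
  co-expressed-condition counts fitted by maximum likelihood to a normal
  distribution truncated to `[0, m]` (Nelder–Mead on location and
  log-scale; a constant sample degenerates to a point mass). Size-matched
  nulls are the default because the count distribution shifts strongly
  with set size; a pooled null is available. The fit is validated by
  parameter recovery (location and scale within 0.2 on a 2000-draw
  sample) and the survival function against numerical quadrature.
* **Dense connectivity.** The module's edge count `m_S` among its
  `C(k,2)` pairs is referred to `Hypergeometric(N=C(n,2), M=|E|,
  K=C(k,2))`, i.e. the probability that as many of the `C(k,2)` drawn gene
  pairs are edges; validated against exact combinatorial summation on all
  small instances.

Modules receive competition ranks per criterion (rank = 1 + number of
strictly smaller p-values); the overall rank is the mean of the two, with
residual ties broken by size then gene list. The redundancy filter walks
the ranked list top-down and keeps a module iff its gene set is not
contained in the union of the kept modules' genes (single-module
containment is available as a variant); an optional `top_n` stops after
keeping that many modules.

## Assessment metrics

Enrichment is a one-sided hypergeometric test of each term annotating a
module gene, against the analyzed (post-filter) gene background — not the
genome — with Benjamini–Hochberg correction over all (module, term) tests
of the run (Bonferroni optional). Term *level* is the shortest directed
path from an ontology root (multiple roots: minimum). Defaults: corrected
p < 0.05, deep level ≥ 7 ("level 7 or higher", i.e. 7, 8, 9, …), core
level ≤ 3.

* **ER** = 100 × (modules with ≥ 1 enriched deep term) / modules.
* **COV** = 100 × (dataset terms enriched in ≥ 1 module) / (terms
  associated with any background gene).
* **IC** = 100 × mean over genes (in ≥ 1 module, with ≥ 1 term) of
  `e_g / t_g`, where `t_g` counts the gene's terms and `e_g` those
  enriched in at least one module containing the gene. IC rewards
  overlapping collections that expose several functional contexts of one
  gene; any partition of the genes caps each gene's contribution at its
  single module.
* **OMPSDF** counts unordered module pairs that (i) overlap in genes,
  (ii) share no enriched core-level term, and (iii) share a gene carrying
  two deep terms, one enriched in each module exclusively. Partitions
  necessarily score 0 (condition (i) never holds).

## Expression prefilters

`variance_filter` retains genes with at least one value strictly outside
mean ± k·sd (k = 1.5 by default), with mean and *sample* (n−1) standard
deviation over the gene's non-missing values; an interval in value units
requires the standard deviation, and the multiplier is a parameter so a
literal variance-based interval can be reproduced. Note the boundary case:
a value exactly on the interval edge is *not* retained.
`fold_filter` retains genes deviating from their mean by ≥ `min_dev` (1.0
log2 units ≙ 2-fold) in ≥ `min_samples` (2) samples; inclusive comparison
("at least 2-fold"). Whether fold variation is assessed on log or linear
ratios is a modeling choice; the filter assumes log2 input. Both filters
are monotone in their thresholds, which is property-tested.

## Synthetic benchmark generator

The generator emulates the structure the DCB definition assumes: an
Erdős–Rényi background network (a configuration-model background is out of
scope) into which each *plant* is wired as a connected subgraph with
exactly `⌈density·C(k,2)⌉` edges (random recursive tree plus random extra
edges; background edges inside a plant are replaced by the wiring).
Expression is built from three layers:

* **planted signatures** — on each planted condition the plant's members
  are drawn uniformly within an ε-band around a center of magnitude 2–4
  log2 units (random sign), so the planted set satisfies the co-expression
  constraint *by construction*. Plants sharing a condition draw centers at
  least 2ε apart so distinct modules remain distinguishable in the
  expression channel;
* **unstructured background** — every other cell is N(0, `background_sd`)
  with `background_sd` = 1.0 log2 units, the variability of a typical fold
  change compendium;
* **measurement noise** — N(0, `noise_sd`) added to *every* cell;
  `noise_sd` = 0 is the noise-free setting and is the dial along which
  recovery degrades monotonically (property-tested on medians across
  seeds). Placing the degradation dial on all cells rather than only
  outside planted subspaces is deliberate: a generator whose "noise-free"
  setting flattens the background to a constant would make every gene pair
  co-expressed everywhere and no planted module identifiable.

Missing values are masked outside planted cells only, so missingness never
destroys a planted witness. The standard benchmark is five disjoint plants
of sizes 4–8 at internal density 0.7 with 3-condition subspaces in a
100-gene ER(p = 0.05) background over 10 conditions at ε = 0.5; noise-free
and fully observed, it is recovered exactly (all Jaccard 1.0) by
enumeration plus merging. One residual failure mode exists at roughly the
10⁻³-per-seed level: a small plant's members may by chance cluster within
ε in ≥ `d_min` background conditions together with an extra gene, creating
a larger DCB that legitimately subsumes the plant under the maximality
definition. This is correct exhaustive-search behavior on an unlucky
instance, not a defect, and is left as is.

What passing these tests does **not** show: real interaction networks are
scale-free-ish and noisy in their edges (false positive/negative
interactions are not modeled), real expression noise is condition- and
gene-correlated, and real GO annotations are incomplete and biased. The
benchmark validates algorithmic correctness, not biological performance.

## Problem sizes and numerical choices

Randomized cross-checks run on instances of ≤ 12 genes and 6 conditions,
where brute force over all gene subsets is exact and fast; the planted
benchmark uses 100 genes. These sizes were chosen so that the reference
enumerator remains an independent oracle while exercising every code path;
the lattice search itself scales to the thousands of genes of organism-
scale networks after edge pruning. Ranking defaults to 2000 null samples
per module size (the standard sample count; reduce for quick runs).
Truncated-normal fitting uses Nelder–Mead with tolerances 1e-6/1e-8 and a
floor of 1e-6 on the initial scale; degenerate (constant) samples are a
point mass with p-values 1/0 on either side. All sampling is driven by a
single user-supplied seed; every stage is deterministic given its inputs,
including tie-breaks (documented above). Gene identifiers are opaque,
case-sensitive strings; genes present in only one of the network and
expression inputs are dropped with a logged report.

## Known limitations

* Exhaustive enumeration below γ = 0.5 is supported only via the capped
  brute-force path; the additional pruning theory needed at scale is out
  of scope.
* Edges are unweighted and undirected; confidence-scored or directed
  interactions are not modeled.
* The merge fixpoint is quadratic in the number of modules per iteration —
  fine for filtered collections, slow for very large unmerged outputs.
* GO handling expects pre-tabulated gene→term and child→parent tables;
  evidence codes and term obsolescence are the caller's concern.
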