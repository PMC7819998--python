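# Methods

## Scope and model

`netsep` treats the interactome as an undirected, unweighted simple
graph over opaque gene/protein identifiers and a disease as a set of
such identifiers (one GMT line per disease).  Three questions are
answered, in order: does a gene set localize into a network module; how
separated are two modules; and what disease-level structure do the
pairwise statistics imply.  Everything downstream of graph loading is
deterministic given a run seed.

All distance-based statistics are computed on the largest connected
component (LCC) of the interactome.  Gene-set members outside the LCC
are dropped with a logged warning.  This guarantees every hop distance
`d(a, b)` is finite; the alternative (keeping unreachable pairs and
defining `d = ∞` or a capped value) would make proximities depend on an
arbitrary cap.  For well-curated interactomes the LCC holds nearly all
nodes, so the restriction is mild.  Identifier matching is exact,
case-sensitive string equality — alias resolution is upstream curation
and deliberately out of scope.

## Localization ("module significance")

The induced subgraph of a mapped module is summarized by three metrics:
total edge count, LCC node count, and edge count within that LCC.
Component ties are broken by size, then by the lexicographically
smallest member, which can only affect the reported LCC edge count.

The null model draws random node sets with the module's size and degree
profile.  Degrees are binned into base-2 logarithmic intervals
`[2^k, 2^(k+1))`; sparse bins are merged upward until each holds at
least `min_occupancy` nodes (default 100; the top bin may absorb a
short tail).  Each replicate draws, without replacement and per bin,
exactly as many nodes as the module has in that bin, so the per-bin
degree histogram of every null sample equals the module's exactly.
Samples may reuse original module members — the null is conditional on
the degree profile, not on avoiding the observed set.

With `R` replicates (default 1000) each metric is z-scored against the
null using the population standard deviation (ddof = 0), and assigned a
one-tailed upper-tail normal p-value — localization is a one-sided
hypothesis ("more structure than chance").  The empirical permutation
rank `(1 + #{null ≥ obs}) / (R + 1)` is reported alongside as a
diagnostic; the normal approximation is the primary p-value.  If the
null is degenerate (zero s.d., e.g. a module forced to be the entire
bin), z is undefined, p is reported as 1 (observed ≤ mean) or 0, and a
degeneracy flag is set.

## Separation

Proximity is the mean nearest-neighbor hop distance between two sets
(both directions, normalized by `|A| + |B|`).  Two conventions are
load-bearing:

* **Self-proximity excludes the node itself.**  Otherwise `p_AA ≡ 0`
  and `s` could never be negative, and the statistic could not express
  overlap at all.
* **Shared members of distinct sets contribute distance 0.**  Member
  overlap is exactly what should pull `s` negative.

Sets are compared as sets: when two differently-named modules have
identical members they are treated as the same module (self-exclusion
applies), giving `s = 0` exactly.

The permutation null replaces *both* sets with independent
degree-matched samples (same binning machinery as localization) and
recomputes `s`, `R` times.  The observed `s` is z-scored (ddof = 0) and
given a two-tailed normal p-value — unlike localization, either
direction (overlap or separation) is interesting.  Labels at level
0.05: `cognate` (s < 0, p < 0.05), `non_cognate` (s > 0, p < 0.05),
otherwise `uncertain`; a degenerate null forces `uncertain`.

The generalized measure `s̃ = sigmoid(α·s/pval) − 0.5` maps the
(effect, significance) pair into (−0.5, 0.5): saturated for strong,
significant separation or overlap, near zero when p is unimpressive.
The default smoothing α = 0.3 keeps |s̃| below ≈0.1 for insignificant
p-values.  Numerics: the sigmoid is evaluated with `scipy.special.expit`;
p-values below 1e-308 raise unless the caller opts into saturation mode
(then ±(0.5 − ulp) is returned); float results that would round onto
±0.5 are nudged to the nearest representable interior value, honoring
the open bound.

Performance: distances come from one BFS sweep
(`scipy.sparse.csgraph`) cached in a `ShortestPaths` object, so each of
the thousands of permutation replicates reduces to sub-matrix indexing.
Memory is 8·n² bytes — fine up to a few tens of thousands of nodes,
which covers published consolidated interactomes (~1.6 × 10⁴ proteins).

## Diseasome

The pairwise matrix computes `separation_significance` for every
unordered pair in sorted-label order, each pair seeded by a sub-seed
derived from the run seed and the two names (SHA-256, reduced below
2³¹), so results are independent of input order and parallelization.

**Clustering.**  Complete-linkage agglomeration on `s` as the distance.
Because `s` can be negative, condensed distances are shifted by
`−min(s)` when needed; a uniform shift cannot change complete-linkage
merge order (the maximum over a cluster pair shifts uniformly), and the
shift is recorded so heights can be mapped back.  Leaf order is
deterministic: at every merge the smaller cluster leads; equal sizes
break ties by the lexicographically smallest leaf.  The dendrogram is
exported as Newick with branch lengths as height differences.

**Edge rule.**  For disease D, let `N_D` be the negative `s̃(D, ·)`
values and `t_D` their 75th percentile (linear interpolation on the
sorted values — the estimator had to be fixed somewhere, and the
interpolating one is numpy's default).  D admits the edge to E when
`s̃(D,E) ≤ t_D`.  Admission uses `≤`, not `<`: strongly cognate pairs
saturate `s̃` to numerically identical values near −0.5, and a strict
inequality would then reject *all* of a node's equally-strong partners
on an exact tie — on continuous data the two rules agree almost surely,
so `≤` is purely tie handling.  The final edge set is the union of both
endpoints' admissions (the rule is written from one module's
perspective; the union keeps the graph symmetric without discarding
admitted edges).  An intersection variant is available behind
`edge_rule="intersection"`.  Diseases with no negative `s̃` admit
nothing of their own and stay isolated unless a partner admits them.

**Cross-collection comparison.**  To compare one module collection
against another (e.g. expression-derived modules vs. curated disease
genes supplied as GMT), every cross pair plus every within-second-
collection pair is tested, with conventional significance stars
(0.05 / 0.01 / 0.001).  The interesting readout is whether
cross-collection separations run lower than the second collection's
internal ones.

## Synthetic benchmarks

The generator emulates the two properties of real inputs the statistics
feed on: a heavy-tailed interactome and gene sets with controlled
localization and overlap.

* **Graph**: Barabási–Albert preferential attachment (`n` nodes, `m`
  edges per newcomer, hence `m(n−m)` edges) — connected by
  construction, heavy-tailed enough that degree binning is non-trivial
  (max degree ≥ 5× median at `m ≥ 2`, `n ≥ 1000`).  Chosen over a
  configuration model because connectivity and heavy tails come with
  two parameters; this is test plumbing, not a biological claim.
* **Single module** (`plant_module`): `⌈cohesion·size⌉` members grown
  as a connected subgraph by randomized breadth-first expansion, the
  rest uniform random.  Cohesion 1 guarantees a connected induced
  subgraph.
* **Module family** (`plant_module_family`): classes are anchored at
  greedily chosen mutually far-apart nodes, and each class claims a
  compact connected ball around its anchor (union of class module
  sizes, +50% slack).  Pairwise shared members form dedicated pools —
  pools of different pairs are disjoint, so requested overlap counts
  are realized exactly — grown round-robin with each new pool node
  preferentially adjacent to a *different* pool of the class.  Unique
  members prefer candidates adjacent to every partner module, then the
  module's own pools.  This makes cognate classes genuinely coalesce:
  with connected modules, `s ≥ −overlap_fraction` analytically, so
  overlap is only detectable when non-shared members actually sit next
  to the partner module.  Realized (not requested) cohesion and overlap
  are recorded in `BenchmarkTruth`; interleaving can fragment a
  module's own induced subgraph, which the truth file makes visible.

Default study conditions for benchmarks: 2,000-node graphs at
attachment 3, modules of 30 genes, 40% pairwise overlap within a class
(50% for the diseasome-structure benchmark, where the minimal 4-disease
network needs all three within-class pairs to tie at saturation for the
two-value percentile rule to admit a full triangle).

What the generator does **not** emulate: the real interactome's exact
degree sequence, clustering/motif structure, edge noise, or
expression-derived gene-set noise.  Passing benchmarks validates the
implementation and calibration of the statistics — not biological
discovery on real data.

## Problem sizes and tolerances in the test suite

Statistical tests run at sizes a laptop handles in minutes: exhaustive
oracle checks on ~200 random graphs of ≤ 10 nodes; Monte-Carlo vs.
enumerated null on the 6-cycle at R = 1000 (agreement within 3 standard
errors); type-I calibration over 200 uniform-random modules on a
2,000-node graph (99% binomial band around the nominal 5%);
planted-truth recovery over 50 seeded benchmark runs (≥ 90% required);
diseasome structure on 3 seeds; clustering shift-invariance on 100
random matrices.  Tolerances follow from the sampling distributions
(standard errors, binomial quantiles), not from tuning.

## Known limitations

* The normal approximation to permutation z-scores inherits the usual
  caveats for discrete, skewed nulls; the empirical rank is reported
  alongside for localization.  Observed type-I rates sit near but not
  exactly at nominal (e.g. 7.5% at the 5% level in the calibration
  test's conditions).
* The dense distance matrix limits graphs to tens of thousands of
  nodes; beyond that a per-pair BFS backend would be needed.
* The percentile edge rule is unstable for very small diseasomes (few
  negative values per node); with two negatives the 75th percentile
  keeps only the stronger unless they tie.
* Weighted or directed interactomes, alias resolution, and alternative
  proximity kernels are out of scope.
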