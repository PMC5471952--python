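# Methods

## Problem

Polychromatic flow cytometry measures ten or more fluorescence channels per
cell, producing an events x channels matrix that cannot be inspected
directly.  The package synthesizes 2D (or 3D) embeddings of such data that
approximately preserve pairwise distances, so that the geometry an analyst
sees — which cells sit together, which sit apart — is a faithful image of
the original channel space.  Fidelity is measured by *distortion*: for a
pair (x, y) projected to (x', y'), distortion(x, y) = |d(x', y') - d(x, y)|,
summarized by its maximum and mean over all pairs.  Unlike stress-minimizing
methods (classical or metric MDS), which optimize an average, the
synthesizer enforces a hard per-pair tolerance and therefore targets the
*worst-case* distortion.

Original-space distances d(x, y) use the Manhattan metric by default (the
same metric that defines the cell network below); Euclidean is available via
`metric=`.  Projected-space distances d(x', y') are always the plane's own
Euclidean norm — the norm the synthesis constraints control.  Mixing a
Manhattan original space with a Euclidean view plane is a deliberate
modeling choice inherited from the method's construction; run reports flag
it.

## The synthesis core

Targets are placed on an unsigned b-bit integer grid.  Given a d x d
distance matrix D, `scale_distances_to_grid` maps the largest distance to
2^b - 1 and rounds: D_int = round(D * scale).  The synthesizer then searches
for grid points R_1..R_d (k = 2 or 3 axes, b bits each) satisfying the
multiplicative band

    (1 - eps) * D_int[i,j]^2  <=  ||R_i - R_j||^2  <=  (1 + eps) * D_int[i,j]^2

for every pair.  Because squared grid distances are integers, the band is
enforced through the exact integer thresholds L = ceil((1-eps) D_int^2) and
U = floor((1+eps) D_int^2); every returned embedding is re-checked against
them post hoc (the *band contract* — the module's primary assertion).

Coordinates are synthesized l high-order bits at a time (b/l iterations).
After s bits each point is confined to an axis-aligned sub-square of side
2^(b-s); interval arithmetic gives the exact minimum and maximum achievable
squared distance between two sub-squares (each bound is attained by some
completion, because the squared distance separates over axes).  One
iteration is the decision problem: choose one l-bit block per point per axis
so that every pair's achievable interval still intersects its band
(upper threshold applied to the interval minimum, lower threshold to the
interval maximum).  At the final iteration the intervals collapse to single
values and the constraint degenerates to the exact band.  An alternative
"optimistic" reading that applies both thresholds to the interval maximum is
available (`literal_eq2=True`) for fidelity experiments; it is not the
default because it lets early iterations keep sub-squares none of whose
completions can satisfy the lower bound.

### The decision search

Each iteration's decision problem is solved by a complete backtracking
search: points are assigned one at a time; a candidate block is pruned if
any pair with an already-extended point, or any pair with a not-yet-extended
point (using its pre-step interval — a necessary condition), leaves the
band.  Iterations are linked by chronological backtracking: when a later
iteration exhausts its models, the previous one advances to its next model,
so the search is complete for the entire b-bit problem, bounded by a global
node budget (`node_budget`, default 200 000 candidate extensions; exceeding
it raises a distinguishable budget signal that auto-epsilon mode treats as
infeasible-at-this-eps).

Completeness lives in the pruning; *speed and solution quality* live in the
value ordering: candidate blocks are tried in order of proximity to a
continuous seed layout (Torgerson classical scaling of D_int followed by 100
SMACOF iterations toward the integer targets).  The seed carries no
correctness weight — it only decides which feasible model the search reaches
first.  Two symmetry reductions are applied: grid reflections allow pinning
point 1's first block to the low half of every axis, and the seed layout is
reflected to match.  The same constraint system is emitted as SMT-LIB 2
QF_BV text (`encode_refinement_smt2`) with identical integer thresholds, so
any conformant external bit-vector solver can be swapped in as the
per-iteration backend.

### Choosing epsilon, and the final polish

Small eps means high fidelity but a hard decision problem; large eps is easy
but loose.  `find_min_epsilon` bisects on (0, 1] (resolution `tol`, default
0.01) and returns the smallest eps whose synthesis succeeds, with its
embedding.  Feasibility is monotone in eps since the band only widens.

A model inside the band may still sit at the band's edge.  A band-preserving
local descent therefore follows synthesis: single-coordinate moves over
geometrically spaced steps (64, 32, ..., 1 grid units) are accepted only if
every pair of the moved point stays inside the integer band *and* the
(max, sum-of-squares) additive-distortion objective strictly decreases.
The band contract is thus never weakened; the embedding moves toward the
band's interior optimum.  Disable with `polish=False`.

Defaults b = 10, l = 2 place coordinates on a 1024-grid — fine enough that
the quantization floor (about sqrt(2) * k / scale in data units) is small
against typical cytometry distances, coarse enough that ten-point problems
solve in seconds on one core.

## The network pipeline (large N)

Synthesizing all N cells directly is infeasible beyond a few dozen points,
so larger inputs go through a structural reduction:

1. **Thresholded cell network.**  Cells are nodes; an edge joins two cells
   whose Manhattan distance is at most T (closed inequality).  As T sweeps
   from 0 to the diameter the network moves from N isolated nodes to a
   clique.
2. **Threshold selection.**  T is chosen to maximize the Shannon entropy of
   the degree distribution over a 64-quantile grid of the pairwise
   distances (ties toward the smallest T); entropy of the component-size
   distribution is available via `property="components"`.
3. **Communities.**  Walktrap random-walk agglomeration (walk length 4,
   python-igraph backend), run per connected component, merge sequence cut
   at maximal modularity; isolated nodes become singletons.
4. **Structural points.**  Each community C_i contributes its centroid O_i
   plus the centroids E_i^j of its k-means split into 3 parts (2D target;
   4 parts for 3D), giving d = 4n (or 5n) structural points.  Communities
   smaller than the split count are padded with centroid copies (with a
   warning) so d is invariant.  Component centroids are ordered
   lexicographically for stable indexing.
5. **Synthesis** runs on the structural points' distance matrix only.
6. **Placement.**  Every remaining cell is positioned by multilateration:
   its original-space distances to its community's component centroids
   (times the grid scale) are matched against those centroids' synthesized
   positions by solving the linearized squared-distance system in least
   squares — exact for consistent distances, residual-minimizing otherwise.
   Degenerate (collinear/coplanar) anchor sets fall back to adding the
   community centroid as an extra anchor, then to placing at the community
   centroid with a warning.

### A caution on threshold selection

On synthetic multi-population data the entropy-maximizing threshold does
*not* land in the regime where communities equal populations.  Degree
entropy grows with degree spread, which peaks when the largest scale present
is partially connected — either within populations (small T) or between
them (large T) — and has a pronounced minimum exactly where each population
is a dense, separate component.  Sweeps over 1000-cell three-population
clouds show population recovery (adjusted Rand index near 1) only inside
that entropy valley; at the entropy argmax the recovered communities merge
or subdivide populations (ARI about 0.5).  The selection rule is kept as
specified — it is the method's stated construction — but users clustering
multi-population data should expect to supply a threshold (``threshold=``)
informed by the distance histogram rather than rely on the entropy
criterion.  This limitation is intrinsic to entropy maximization over
node-level property distributions, not to the community detector.

## Baselines and evaluation

*Classical MDS*: Torgerson scaling — double-center -1/2 D^2, top-k
non-negative eigenpairs, eigenvectors scaled by sqrt(eigenvalue), signs
fixed by making each axis's largest-magnitude loading positive.  Exact for
Euclidean-embeddable matrices; cross-checked in tests against scikit-bio's
PCoA.  *Random projection*: an m x k matrix of i.i.d. N(0, 1/k) entries,
preserving squared Euclidean distances in expectation
(Johnson–Lindenstrauss).  Both are compared to the synthesizer on identical
subsamples with identical metrics; published benchmark ratios are truncated
(not rounded) to the printed precision — 3 decimals per dataset, 2 for
summaries — which is the convention the shipped printed tables follow.

## Synthetic data

`generate_flow_like_cloud` draws a Gaussian mixture in channel space,
clipped at zero (the instrument floor): by default 3 populations, 12
channels, population means uniform in [200, 900] per channel, per-channel
standard deviation 40, equal weights, optional rare population below 5%.
These defaults put pairwise Manhattan distances in the low thousands — the
scale of the published distortion tables.  `sample_benchmark_instance`
yields the benchmark unit: 10 cells x 12 channels with its distance matrix.

What the generator does *not* emulate: spectral spillover/compensation,
log-normal or bimodal marker distributions, doublets and debris, or
correlated channels.  Green tests on this generator therefore demonstrate
algorithmic correctness (distance preservation, recovery of planted
structure) — not robustness to instrument artifacts.

`brute_force_min_max_distortion` is the independent oracle for the
synthesis core: for d <= 4 points, b <= 3 bits, k = 2 it enumerates every
grid placement and returns the true minimum of the maximum additive
distortion (the search runs in float32 for memory; the returned optimum is
recomputed in float64 from the argmin placement).  Measured against it, the
full synthesizer (auto-epsilon, bisection tolerance 0.005) stays within a
third of a grid unit of optimal on random realizable instances — well under
one grid-cell diagonal — and never below it.

## Numerical choices and degeneracies

- Integer thresholds L, U make the band check exact; no floating-point
  comparison decides feasibility.
- Pairs with D_int = 0 (duplicated structural points) force co-location.
- An all-zero distance matrix cannot be scaled and is rejected.
- k-means uses k-means++ with 10 restarts and a fixed seed derived from the
  master seed via named substreams (`subsample`, `kmeans-c<i>`, `rp`,
  `cells`, `popspec`), so a single seed reproduces a whole run.
- Walktrap itself is deterministic (exact transition probabilities); the
  `seed` argument of `detect_communities` exists for interface uniformity.
- FCS reading covers FCS 3.0/3.1 list-mode files with float or 32-bit
  integer storage in either byte order; compensation and intensity
  transforms are never applied implicitly (a `transform` hook on
  `RunConfig` accepts a user-supplied one).

## Problem sizes used in tests

The shipped test and reproduction workloads are sized for a single core:
10-point x 12-channel benchmark units (30 printed datasets, 10 synthetic
seeds for the head-to-head), 50 randomized band-contract instances with
d <= 8 and b <= 10, 20 exhaustive-oracle instances at d <= 4 and b = 3, and
one 1000-cell pipeline run.  The synthesizer itself handles structural sets
of a few dozen points; beyond that the network pipeline is the intended
path.
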