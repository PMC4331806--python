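# Methods

## Model and procedure

The pipeline turns a weighted undirected PPI network into a partition of
its proteins in three stages.

**Similarity and embedding.** For every edge (i, j) the similarity mixes
the unweighted aggregation coefficient — (common neighbors + 1) divided by
the smaller endpoint degree — with its weighted analogue, balanced by η.
Similarity is defined on edges only: both terms describe properties of an
existing interaction, and a dense all-pairs matrix would degenerate the
row-sum normalization that follows. The similarity matrix is then
symmetrically normalized by its row sums (a normalized adjacency, not a
subtraction-form Laplacian), so cluster structure lives at the *top* of its
spectrum; the spectrum of this matrix lies in [−1, 1]. The embedding takes
the eigenvectors of the three largest eigenvalues, in decreasing eigenvalue
order, and scales each row to unit Euclidean norm. The "+1" in the
unweighted term is kept exactly as defined and not clamped, even though it
can push the term above 1 when common neighbors are plentiful.

Reproducibility choices: each eigenvector's sign is fixed by forcing its
first component of magnitude above 1e−12 positive; eigenvalue ties are
resolved by the symmetric eigensolver's ascending order, then reversed.
Isolated nodes produce all-zero similarity rows, hence all-zero embedding
rows, which are left at the origin (they end up clustered together — a
deliberate "unconnected proteins" sink rather than an error).

**Synchronization clustering.** Embedded objects within Euclidean distance
ε of each other (boundary inclusive) couple through the phase update

    x(t+1) = x(t) + (1/|N_ε(x)|) · Σ_{y ∈ N_ε(x)} sin(y(t) − x(t)),

applied synchronously (Jacobi-style) from the time-t snapshot. The
neighborhood in this normalization is *closed*: the object's own term
contributes sin(0) = 0 to the sum but does count in the divisor. This makes
an isolated object an exact fixed point with no special-casing, and gives a
coupled pair the separation recurrence s → s − sin s, which contracts
cubically (below 1e−6 within a handful of steps). Normalizing by the open
neighborhood instead would give s → s − 2·sin s, whose contraction ratio
tends to 1 and which therefore synchronizes pairs only polynomially slowly;
the closed form is the one consistent with a neighborhood defined as
{y : dist(x, y) ≤ ε}, which always contains x itself.

A set S is an ε-neighborhood closure when every member's closed
ε-neighborhood (restricted to still-unclustered objects) equals S —
equivalently, S is a connected component of the ε-graph in which every
member already sees the whole component. Such a set is guaranteed to
synchronize fully, so the clustering loop declares every closure a cluster
immediately, freezes its members (they stop moving and stop attracting;
coupling is restricted to the unmarked set), and applies one coupling step
to the remainder. An object with no ε-neighbor is its own singleton
closure — the outlier behavior. If the dynamics have not resolved
everything after `max_steps` (default 100) coupling steps — possible for
oscillating configurations — each remaining ε-graph component becomes a
cluster, with a warning. The output is always a full partition.

**Radius optimization.** Clustering quality is the weighted modularity
fval: per cluster, the unweighted in-degree ratio 2m/(2m+n) raised to ρ
times the weighted ratio w_in/w_tot raised to 1−ρ. In-degree counts each
internal edge twice (once per endpoint), which keeps both factors in [0, 1]
and each cluster's contribution in [0, 1]; a cluster with no incident edges
contributes 0. At ρ = 1 only the unweighted term matters, at ρ = 0 only the
weighted one.

The firefly search runs 6 candidate radii for 30 iterations within
[mean nearest-neighbor distance, embedding diameter] — below the lower
bound everything is a singleton, above the upper everything is one cluster.
Intensities are (re)computed once per iteration and memoized on the radius
rounded to 12 decimals; within an iteration fireflies sweep in index order,
each dimmer firefly moving once toward every brighter one (attractiveness
β₀e^{−γr²}, r the 1-D distance between radii, plus the α-scaled uniform
perturbation), with positions clipped — not reflected — back into the
interval. The brightest firefly stays put. A single seeded generator drives
initialization and all perturbation draws in a fixed order, so identical
seeds give identical traces and results. The hierarchical-scan baseline
starts at the mean 3rd-nearest-neighbor distance with the 4-NN/3-NN gap as
increment (falling back to a linear subdivision of the remaining range if
that gap is non-positive), stops early once one cluster swallows
everything, and breaks objective ties toward the smaller radius.

**Evaluation.** Precision credits each predicted cluster with its largest
node overlap over reference complexes, normalized by total predicted size;
recall is the mirror image over reference complexes. Matching is
independent per cluster (a complex may be the best match of several
clusters); recall's denominator is the multiset total over complexes, so
overlapping complexes count their shared proteins once per complex. The
f-measure is the harmonic mean 2pr/(p+r), defined as 0 when both are 0.
The Pearson correlation helper uses the sample (n−1) standard deviation
and refuses constant input.

## Parameters

| parameter | default | meaning |
|---|---|---|
| η | 0.5 | balance of unweighted vs weighted edge aggregation (dimensionless) |
| ρ | 0.8 | modularity exponent: weight of the unweighted connectivity ratio |
| β₀ | 1.0 | maximum firefly attractiveness (at distance 0) |
| γ | 1.0 | light absorption: decay rate of attraction with squared distance |
| α | 0.9 | step size of the uniform random perturbation, in [0, 1] |
| fireflies | 6 | swarm size |
| maxiter | 30 | firefly iterations |
| max_steps | 100 | cap on synchronization coupling steps per clustering |
| merge_tol | 1e−9 | coordinate coincidence tolerance for exact-synchrony detection |

Edge weights default to 1.0 when the input carries no weight column, which
makes the weighted terms of the similarity and the objective well defined
for unweighted networks. Duplicate edges collapse keeping the maximum
weight (idempotent under file concatenation); self-loops are dropped with a
warning.

## Synthetic data

The planted-partition generator samples every within-module pair as an edge
with probability p_in and every between-module pair with p_out (defaults
0.9 / 0.02, three modules of eight — small enough to verify exhaustively,
large enough that the embedding separates modules), with constant or
uniform edge weights. It emulates exactly what the method assumes — dense
modules, sparse boundaries — and nothing else: no scale-free degree
distribution, no hub proteins, no overlap between complexes, no missing or
spurious interactions beyond the Bernoulli noise. Passing the recovery
tests therefore shows the pipeline correctly identifies clearly modular
structure; it does not certify performance on real interaction maps, whose
reference complexes are partial, overlapping and noisy.

## Numerical choices and limitations

- Closure detection, neighborhoods and the objective are exact
  (combinatorial); the only tolerances are the eigensolver's and the
  1e−12 sign-fix threshold.
- The ε-graph is built from a dense pairwise-distance matrix, O(n²) memory:
  appropriate for networks up to a few thousand proteins, not for
  interactome-scale graphs.
- The firefly search is a metaheuristic: it carries no optimality
  guarantee, only the reproducibility of its seed and the empirical
  behavior checked in the tests (it matches a fine grid search on smooth
  unimodal objectives and never does worse than the hierarchical scan on
  the planted benchmark).
- Only partitions are produced; overlapping complexes cannot be predicted
  even when the reference contains them, which bounds attainable recall on
  overlapping references.
- The objective's validation requires the clusters to partition exactly
  the network's nodes; evaluating externally produced clusterings that
  omit nodes is not supported through `modularity_objective`.
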