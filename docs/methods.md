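# Methods

## Problem setting

A ligand–receptor (LR) analysis of a multi-sample scRNA-seq cohort yields,
for every patient sample *k*, a directed weighted graph
G_k = (V, E_k, w_k): nodes are cell types (shared across the cohort), a
directed edge (a, b) says cell type *a* signals to cell type *b*, and the
weight is the summed LR interaction score for that directed pair. `cccot`
equips such cohorts with a Wasserstein geometry that respects both edge
direction and the shared communication topology, and clusters samples in
that geometry.

## Shared topology graph and its Markov chain

All samples are modelled as signals on one support: the union of directed
edges over the cohort. The **shared topology graph (STG)** is the directed
line graph on that union — vertex = directed cell-pair edge, and an STG edge
u' → v' exists when the target cell of u' is the source cell of v'
(consecutive communication events). Its weight is the fraction of samples
containing both original edges, so co-occurring interactions form
high-conductance corridors. A self-loop edge (a, a) is head-to-tail
compatible with itself; its STG diagonal entry is its own frequency.

The walk on the STG is `P = (1 − α) D⁻¹W + α J/E`. The teleportation term
(default **α = 0.05**) makes P strictly positive, hence irreducible and
aperiodic, which the hitting-time machinery requires; the default is kept
small so the chain is perturbed minimally. Rows of W with no outgoing
compatible edge are replaced by the uniform distribution before mixing (the
standard dangling-node convention). Mixing is done at the transition level,
not the adjacency level, following the usual teleportation construction.

## Hitting-time ground cost

With π the stationary distribution of P and
Q_ij = P(hit j before returning to i | start at i), the normalized
hitting-time matrix T gives the ground cost C = −log T (diagonal forced to
exactly 0). Two normalizations of T are implemented:

* `as_printed` (default): T_ij = π_i^{1/2} π_j^{1/2} Q_ij. Since
  √(π_i π_j) ≤ 1/2 and Q ≤ 1, off-diagonal costs are bounded below by ln 2.
  This matrix is generally asymmetric.
* `similarity`: T_ij = π_i^{1/2} π_j^{−1/2} Q_ij. By the commute-rate
  identity π_i Q_ij = π_j Q_ji (both sides equal 1/(E_i[τ_j] + E_j[τ_i])),
  this form is symmetric for every irreducible chain and equals
  √(Q_ij Q_ji), so costs are again non-negative.

The two conventions exist because the literature states the exponent of π_j
both ways; both are exposed behind a flag. By default C is additionally
symmetrized as (C + Cᵀ)/2 so that pairwise sample distances are symmetric.
Note the symmetrized `as_printed` cost equals the `similarity` cost plus a
separable term f(i) + f(j) with f = −½ log π ≥ 0, so it inherits the
triangle inequality from the similarity form, which is a metric.

Q is computed exactly, one linear solve per target vertex j: with
A = I − P restricted to V∖{j} and G = A⁻¹, the solution of the system that
additionally absorbs at source i is obtained from the j-only solution by a
rank-one update using column i of G, so all sources share one O(E³)
factorization. Dense factorizations are used up to E = 2000 STG vertices,
far beyond the tested regime (E ≈ 70–80 for a 10-cell-type cohort).

## Transport

Each sample's edge-weight row is normalized to the probability simplex
(balanced transport assumes mass conservation; LR-score totals vary with
sequencing depth, so relative allocation is the meaningful signal). The
DW-OT distance between samples is the Wasserstein distance under C, solved
as an exact linear program (HiGHS; the redundant final marginal constraint
is dropped). Exact LP is the default everywhere distances are consumed —
it is deterministic and cheap at STG scale (~25 ms at E = 75).

Entropic (Sinkhorn) transport, implemented in the log domain throughout,
serves two roles: approximate distances when requested, and barycenters
(below). The default regularization is ε = 10⁻² of the maximum ground cost.
The KL-penalized unbalanced formulation (scaling iterations with exponent
ρ/(ρ+ε), default ρ = 1) relaxes the marginal constraints; its reported value
is the transport cost plus the two ρ-weighted marginal KL penalties, which
vanishes at p = q and approaches the balanced Sinkhorn value as ρ → ∞ on
normalized inputs.

The CORR-OT baseline replaces C by one minus the Pearson correlation of
edge columns across samples (zero-variance columns get correlation 0 by
convention). It sees signal co-variation but not graph topology.

## Clustering

* **k-medoids**: PAM-style alternation on the precomputed distance matrix,
  ties broken toward the lowest index, best of 10 seeded random restarts.
* **k-barycenters**: EM whose centroids are fixed-support entropic
  Wasserstein barycenters on the STG vertices (iterative Bregman
  projections, log domain). E-step: assign each sample to the nearest
  barycenter by exact LP distance. M-step: recompute each cluster's
  barycenter. Initialization seeds barycenters at spread-out samples
  (farthest-point by default; a k-means++-style sampling mode exists because
  either reading of the seeding is defensible). Empty clusters are re-seeded
  with the sample farthest from its current barycenter. The EM is restarted
  (100 restarts by default; tests and the acceptance script use 3–5, which
  suffices under deterministic farthest-point seeding) and the restart with
  the lowest average per-cluster Wasserstein loss wins.

"Loss" is the mean over clusters of the mean member-to-representative
Wasserstein distance. Convergence is declared when assignments are
unchanged and barycenters move less than 10⁻⁶ in L1, capped at 200
iterations. Because the entropic barycenter only approximately minimizes
the exact-LP objective, a monotone safeguard stops a restart the moment an
M-step fails to lower the exact loss; the per-restart loss trace is
therefore non-increasing by construction, and the returned state is always
the one that achieved the last traced loss.

## Synthetic cohorts

The generator emulates the cohort structure such pipelines produce, at the
scale of a small pancreatic-cancer cohort: 10 cell types, a shared
Bernoulli(0.75) directed edge set (~75 directed interactions per sample,
self-loops allowed), two groups of 10 samples. Baseline edge means are
lognormal(0, 0.5); each group designates a hub cell type and multiplies the
mean of edges incident to it (and to no other group's hub, keeping group
signatures disjoint) by the effect size s = 5 — mimicking a disease-linked
cell population with strengthened signaling. Per-sample weights add
multiplicative lognormal(0, σ = 0.1) jitter (LR scores are positive and
right-skewed) and optional independent edge dropout. `downsample_signal`
emulates cell-count robustness experiments by binomial thinning of each
weight treated as a count at resolution 1/scale (scale = 100).

What this generator does *not* emulate: correlated noise across edges,
sample-specific cell-type composition shifts, batch effects, and the LR
inference step itself. Passing recovery tests therefore demonstrate that
the geometry separates groups whose signal differs on topologically
coherent edge blocks under multiplicative noise — not performance on any
real cohort.

## Numerical choices

* Stationary distribution: direct solve of the fixed-point system with the
  normalization row substituted; residual ‖πP − π‖∞ must be < 10⁻⁸.
* Hitting probabilities are clipped to [0, 1] against roundoff; the Q
  diagonal is conceptually 1 and never consumed.
* Sinkhorn/barycenter iterations run entirely in log space (logsumexp), so
  ε = 10⁻² of max cost never underflows; barycenter convergence is < 10⁻⁸
  L1 change (< 10⁻⁶ inside the EM loop).
* All orderings (samples, cell types, edges) are lexicographic, and every
  stochastic step is driven by an explicit seed, so distance matrices and
  clusterings are bit-reproducible.
* Problem sizes in the test-suite and acceptance runs (tens of samples,
  E ≈ 70–80, 3–5 EM restarts, 10⁵ Monte-Carlo walks) were chosen as the
  smallest scales at which every property of interest is exercised
  end-to-end.

## Known limitations

* The E-step computes exact LP distances to every barycenter; at hundreds
  of samples or E in the thousands one would switch the E-step to Sinkhorn
  values.
* Unbalanced transport reports the entropic value; no ε→0 extrapolation is
  attempted.
* Asymmetric (non-symmetrized) costs yield asymmetric distance matrices;
  k-medoids and silhouette then have no guarantees and refuse such input.
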