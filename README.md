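# cccot — optimal-transport clustering of cell–cell communication graphs

Single-cell cohort studies increasingly summarize each patient sample as a
**cell–cell communication (CCC) graph**: nodes are cell types, a directed
edge means the source cell type signals to the target cell type via
ligand–receptor (LR) pairs, and the edge weight is the summed LR interaction
score. A clinically central question is whether patients group by their
communication patterns. `cccot` answers it by giving cohorts of directed,
weighted CCC graphs a Wasserstein geometry that respects both edge
*direction* and the cohort's shared *topology*, then clustering samples in
that geometry. It is aimed at computational biologists working downstream of
LR-inference tools (CellPhoneDB/LIANA-style pipelines) that emit per-sample
edge tables.

## The method

1. **Shared topology graph (STG).** The union of directed edges over all
   samples becomes the vertex set of a directed line graph: vertex = edge
   (a, b); an STG edge (a, b) → (b, c) connects consecutive communication
   events, weighted by the fraction of samples containing both. A
   PageRank-style teleportation term α (default 0.05) makes the walk
   irreducible: P = (1−α)·D⁻¹W + α·J/E.
2. **Hitting-time ground cost.** With π the stationary distribution and
   Q_ij = P(hit j before returning to i | X₀ = i), the cost is
   C_ij = −log(π_i^½ π_j^½ Q_ij) (an alternative symmetric normalization
   −log(π_i^½ π_j^-½ Q_ij) is available; C is symmetrized by default).
   Moving signal mass along frequent, directionally consistent
   communication chains is cheap; against or across them, expensive.
3. **DW-OT distance.** Each sample's edge weights, normalized to the
   simplex, form a distribution on STG vertices; the distance between two
   samples is the Wasserstein distance d_W(G_k, G_l) = min_Γ ⟨Γ, C⟩ subject
   to marginals P_k and P_l, solved exactly as a linear program. Entropic
   (Sinkhorn), KL-unbalanced, and correlation-cost (CORR-OT) variants are
   included.
4. **Clustering.** k-medoids on the distance matrix, or **k-barycenters**:
   an EM algorithm whose centroids are entropic Wasserstein barycenters
   μ_j = argmin_μ Σ_{y_i=j} d_W(G_i, μ) on the STG support, with
   farthest-point seeding and multi-restart selection by the lowest average
   per-cluster Wasserstein loss. Transport plans between cluster
   barycenters highlight which cell-pair interactions shift between groups.

See `docs/methods.md` for assumptions, parameter defaults, and numerical
details.

## Worked example

```python
import numpy as np
import cccot as c

spec = c.CohortSpec(seed=7)           # 10 cell types, 2 groups x 10 samples
cohort, truth = c.generate_cohort(spec)
esm = c.build_edge_signal_matrix(cohort)
line = c.build_stg(cohort)
P = c.regularized_transition(line, alpha=0.05).P
cost = c.htd_cost(P)                  # symmetrized hitting-time ground cost
D = c.pairwise_distances(esm.values, cost, sample_ids=esm.sample_ids)
res = c.k_barycenters(esm.values, cost, k=2, n_restarts=3, seed=0)

print("STG vertices:", line.n_vertices)
print("median within/between distance: %.3f / %.3f" % (
    np.median([D.D[i, j] for i in range(10) for j in range(i + 1, 10)]),
    np.median(D.D[:10, 10:])))
print("labels:", res.labels)
print("ARI vs ground truth:", c.adjusted_rand_index(truth, res.labels))
print("per-cluster Wasserstein loss: %.4f" % res.loss)
print("mean silhouette: %.3f" % c.silhouette(D.D, res.labels)[0])
```

prints

```
STG vertices: 76
median within/between distance: 0.276 / 2.063
labels: [1 1 1 1 1 1 1 1 1 1 2 2 2 2 2 2 2 2 2 2]
ARI vs ground truth: 1.0
per-cluster Wasserstein loss: 0.1884
mean silhouette: 0.864
```

The synthetic cohort plants a 5-fold weight shift on the edges around one
"hub" cell type per group; samples sit ~7x farther from the other group
than from their own, and both clustering algorithms recover the planted
groups exactly (adjusted Rand index 1). The per-cluster loss is the mean
Wasserstein distance of members to their barycenter; the silhouette score
(0.864, near its maximum of 1) confirms two well-separated clusters.

The same pipeline is available from the shell:

```bash
cccot simulate --seed 7 --outdir run
cccot cluster run/cohort.csv --algorithm k_barycenters -k 2 --outdir run
cccot evaluate run/clusters.csv run/true_labels.csv --outdir run
```

Real cohorts enter through `read_edge_table` (long CSV/TSV with columns
`sample, source, target, weight`, or a directory of per-sample files) or
`aggregate_lr_scores` (LR-level tables, summed per directed cell pair).

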