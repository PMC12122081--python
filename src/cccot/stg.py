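"""Shared topology graph (STG): the directed line graph over the edge union.

Every directed cell-pair edge that occurs in at least one sample becomes a
vertex. Two vertices u' = (a, b) and v' = (c, d) are connected u' -> v' when
b == c, i.e. when the two communication events are consecutive (the receiving
cell type of the first is the sending cell type of the second). The weight of
that line-graph edge is the proportion of samples whose graphs contain BOTH
original edges, so random walks — and hence transport — move preferentially
through communication patterns common in the cohort.

Because the line graph may be disconnected, the transition matrix mixes in a
PageRank-style uniform teleportation term with weight ``alpha``, which makes
the chain strictly positive, hence irreducible and aperiodic, so the
hitting-time machinery downstream is well posed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import Cohort, EdgeSignalMatrix, edge_label
from .errors import ParameterError, ValidationError

__all__ = ["LineGraph", "TransitionMatrix", "build_stg", "regularized_transition",
           "write_stg_edges"]


@dataclass(frozen=True)
class LineGraph:
    """Directed line graph over the cohort's edge union.

    ``adjacency[i, j]`` is the co-occurrence proportion of edge-vertices i
    and j when they are head-to-tail compatible, else 0. Vertices follow the
    same lexicographic order as the edge-signal-matrix columns.
    """

    vertices: tuple[tuple[str, str], ...]
    adjacency: np.ndarray  # (E, E) in [0, 1]
    n_graphs: int

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic transition matrix of the regularized STG walk."""

    P: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        rs = self.P.sum(axis=1)
        if not np.allclose(rs, 1.0, atol=1e-12):
            raise ValidationError("transition matrix rows must sum to 1")


def build_stg(cohort: Cohort) -> LineGraph:
    """Build the shared topology line graph of a cohort.

    The vertex set is the sorted union of directed edges; for each ordered
    head-to-tail compatible pair the weight is the fraction of samples
    containing both edges. A self-loop edge (a, a) is compatible with itself.
    """
    if cohort.n_samples == 0:
        raise ValidationError("cohort is empty")
    vertices = tuple(cohort.edge_union())
    if not vertices:
        raise ValidationError("cohort contains no edges")
    E, n = len(vertices), cohort.n_samples
    # membership: samples x edges
    col = {e: j for j, e in enumerate(vertices)}
    M = np.zeros((n, E), dtype=bool)
    for i, g in enumerate(cohort.samples):
        for e in g.edges:
            M[i, col[e]] = True
    cooc = (M.T.astype(float) @ M.astype(float)) / n
    targets = np.array([t for (_, t) in vertices])
    sources = np.array([s for (s, _) in vertices])
    compat = targets[:, None] == sources[None, :]
    return LineGraph(vertices, np.where(compat, cooc, 0.0), n)


def regularized_transition(stg: LineGraph, alpha: float = 0.05) -> TransitionMatrix:
    """Row-normalize the STG adjacency and mix with uniform teleportation.

    ``P = (1 - alpha) * D^-1 W + alpha * J / E``. Rows of W with no outgoing
    compatible edge (dangling vertices) are replaced by the uniform
    distribution before mixing — the standard PageRank convention. For
    ``alpha > 0`` every entry of P is at least ``alpha / E``, so the chain is
    irreducible and aperiodic.
    """
    if not (0.0 <= alpha < 1.0):
        raise ParameterError(f"alpha must be in [0, 1), got {alpha}")
    W = stg.adjacency
    E = stg.n_vertices
    rowsum = W.sum(axis=1)
    P0 = np.empty_like(W, dtype=float)
    dangling = rowsum <= 0
    P0[~dangling] = W[~dangling] / rowsum[~dangling, None]
    P0[dangling] = 1.0 / E
    P = (1.0 - alpha) * P0 + alpha / E
    # exact row-stochasticity against accumulated roundoff
    P /= P.sum(axis=1, keepdims=True)
    return TransitionMatrix(P, alpha)


def write_stg_edges(stg: LineGraph, path_or_buf) -> None:
    """Write the STG as an edge-list CSV (edge_u, edge_v, weight) for inspection."""
    import pandas as pd

    ii, jj = np.nonzero(stg.adjacency)
    labels = [edge_label(v) for v in stg.vertices]
    rows = [(labels[i], labels[j], stg.adjacency[i, j]) for i, j in zip(ii, jj)]
    pd.DataFrame(rows, columns=["edge_u", "edge_v", "weight"]).to_csv(
        path_or_buf, index=False
    )
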