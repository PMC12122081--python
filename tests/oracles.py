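"""Independent reference computations used to check the library.

Each oracle deliberately takes a different route from the implementation it
verifies: Monte-Carlo chain simulation for hitting probabilities, the dual
linear program for transport values, and plain double loops for
co-occurrence and group-by aggregation.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def mc_hitting_probability(P, i, j, n_walks=100_000, seed=0):
    """Estimate P(hit j before returning to i | start i) by simulating walks.

    Returns (estimate, standard_error).
    """
    rng = np.random.default_rng(seed)
    cum = np.cumsum(P, axis=1)
    pos = np.full(n_walks, i)
    active = np.ones(n_walks, dtype=bool)
    hit_j = np.zeros(n_walks, dtype=bool)
    # first step is unconditional (tau >= 1), then absorb at i or j
    first = True
    while active.any():
        idx = np.flatnonzero(active)
        u = rng.random(idx.size)
        nxt = (cum[pos[idx]] < u[:, None]).sum(axis=1)
        pos[idx] = nxt
        hit = nxt == j
        ret = nxt == i
        hit_j[idx[hit]] = True
        active[idx] = ~(hit | ret)
        first = False
    q = hit_j.mean()
    se = np.sqrt(max(q * (1 - q), 1e-12) / n_walks)
    return q, se


def hitting_prob_pair_solve(P, i, j):
    """Per-pair absorbing-chain linear solve (first-step analysis)."""
    N = len(P)
    rest = [k for k in range(N) if k not in (i, j)]
    if rest:
        A = np.eye(len(rest)) - P[np.ix_(rest, rest)]
        h = np.linalg.solve(A, P[rest, j])
        return P[i, j] + P[i, rest] @ h
    return P[i, j]


def ot_dual_value(p, q, C):
    """Optimal transport value via the dual LP: max p.f + q.g, f_i+g_j <= C_ij."""
    E = len(p)
    A = np.zeros((E * E, 2 * E))
    for i in range(E):
        for j in range(E):
            A[i * E + j, i] = 1.0
            A[i * E + j, E + j] = 1.0
    res = linprog(-np.concatenate([p, q]), A_ub=A, b_ub=C.ravel(),
                  bounds=(None, None), method="highs")
    assert res.status == 0
    return -res.fun


def cooccurrence_bruteforce(cohort):
    """STG adjacency by explicit double loops over samples and edge pairs."""
    edges = cohort.edge_union()
    n = cohort.n_samples
    E = len(edges)
    W = np.zeros((E, E))
    for a, u in enumerate(edges):
        for b, v in enumerate(edges):
            if u[1] != v[0]:
                continue
            count = sum(1 for g in cohort.samples
                        if u in g.edges and v in g.edges)
            W[a, b] = count / n
    return edges, W


def random_irreducible_chain(E, rng, sparsity=0.5):
    """Random row-stochastic matrix made irreducible by a small uniform mix."""
    A = rng.random((E, E)) * (rng.random((E, E)) < sparsity)
    A += 1e-3  # strictly positive => irreducible and aperiodic
    return A / A.sum(axis=1, keepdims=True)
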