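"""Hitting-time distance: a ground metric for directed weighted graphs.

Let (X_t) be the Markov chain on the STG vertices with irreducible transition
matrix P and stationary distribution pi (pi P = pi). For an ordered vertex
pair (i, j), Q[i, j] is the probability that the chain, started at i, hits j
before returning to i. The normalized hitting-time matrix T rescales Q by
stationary masses, and the cost is C = -log T with a zero diagonal. Because
the chain is directed, C captures asymmetric reachability: moving signal mass
"with the flow" of common communication chains is cheap, against it expensive.

Two normalization conventions are provided:

* ``as_printed``:   T_ij = pi_i^{1/2} * pi_j^{1/2}  * Q_ij   (generally asymmetric)
* ``similarity``:   T_ij = pi_i^{1/2} * pi_j^{-1/2} * Q_ij   (symmetric)

The similarity form is symmetric for every irreducible chain because of the
cycle-rate identity pi_i Q_ij = pi_j Q_ji (both sides equal
1 / (E_i[tau_j] + E_j[tau_i]), the commute rate), which also shows
T_ij = sqrt(Q_ij * Q_ji) <= 1, so costs stay non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .errors import NumericError, ParameterError, ValidationError

__all__ = ["CostMatrix", "stationary_distribution", "hitting_probabilities",
           "htd_cost", "write_cost_matrix"]

VARIANTS = ("as_printed", "similarity")

#: dense linear algebra up to this many STG vertices, iterative above
_DENSE_LIMIT = 2000


@dataclass(frozen=True)
class CostMatrix:
    """Ground cost over STG vertices: zero diagonal, finite non-negative body."""

    C: np.ndarray
    variant: str
    symmetrized: bool

    def __post_init__(self) -> None:
        if not np.all(np.diag(self.C) == 0):
            raise ValidationError("cost matrix diagonal must be exactly 0")
        if not np.all(np.isfinite(self.C)):
            raise ValidationError("cost matrix entries must be finite")


def _check_stochastic(P: np.ndarray) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValidationError("P must be square")
    if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
        raise ValidationError("P must be row-stochastic")
    return P


def stationary_distribution(P: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Unique invariant distribution pi with pi P = pi, normalized to sum 1.

    Solved directly as the null space of (P^T - I) with the normalization
    row appended; falls back to power iteration for large chains.
    """
    P = _check_stochastic(P)
    N = P.shape[0]
    if N == 1:
        return np.ones(1)
    if N <= _DENSE_LIMIT:
        # replace the last equation of (P^T - I) pi = 0 by sum(pi) = 1
        A = P.T - np.eye(N)
        A[-1, :] = 1.0
        b = np.zeros(N)
        b[-1] = 1.0
        pi = scipy.linalg.solve(A, b)
    else:
        pi = np.full(N, 1.0 / N)
        for _ in range(100_000):
            nxt = pi @ P
            if np.abs(nxt - pi).max() < tol:
                pi = nxt
                break
            pi = nxt
        pi /= pi.sum()
    resid = np.abs(pi @ P - pi).max()
    if resid > 1e-8 or np.any(pi <= 0):
        raise NumericError(
            f"stationary distribution failed: residual {resid:.2e}; "
            "is the chain irreducible?"
        )
    return pi / pi.sum()


def hitting_probabilities(P: np.ndarray) -> np.ndarray:
    """Matrix Q of probabilities of hitting j before returning to i.

    For each ordered pair (i, j), Q[i, j] = P(tau_j <= tau_i | X_0 = i) where
    tau is the first hitting time (>= 1). Computed per target j from one
    absorbing-chain factorization shared across all sources i: with
    A = I - P restricted to V \\ {j} and G = A^{-1}, the solution of the
    system that additionally absorbs at i is obtained from the j-only
    solution x = G b by the exact rank-one update y = x - (x_i / G_ii) G[:, i]
    (which zeroes coordinate i), so each extra source costs O(E) after the
    O(E^3) factorization. The diagonal is set to 1 (a return) and never used.
    """
    P = _check_stochastic(P)
    N = P.shape[0]
    Q = np.ones((N, N))
    if N == 1:
        return Q
    for j in range(N):
        idx = np.delete(np.arange(N), j)
        Prest = P[np.ix_(idx, idx)]
        b = P[idx, j]
        A = np.eye(N - 1) - Prest
        try:
            G = scipy.linalg.inv(A)
        except scipy.linalg.LinAlgError as exc:  # pragma: no cover
            raise NumericError(f"singular absorbing system for target {j}") from exc
        x = G @ b  # x_k = P(hit j before i is even considered | start k), j absorbing
        diagG = np.diag(G)
        if np.any(diagG <= 0):  # pragma: no cover
            raise NumericError(f"ill-conditioned absorbing system for target {j}")
        # per source a: y^(a) = x - (x_a / G_aa) * G[:, a]; Q_aj = b_a + Prest[a] . y^(a)
        rowdot = np.einsum("ak,ka->a", Prest, G)
        Q[idx, j] = b + Prest @ x - (x / diagG) * rowdot
    np.clip(Q, 0.0, 1.0, out=Q)
    np.fill_diagonal(Q, 1.0)
    return Q


def htd_cost(P: np.ndarray, variant: str = "as_printed",
             symmetrize: bool = True) -> CostMatrix:
    """Hitting-time-distance cost matrix C = -log T on the STG vertices.

    ``variant`` selects the normalization of T (see module docstring);
    ``symmetrize`` averages C with its transpose so the downstream transport
    cost — and hence the pairwise sample distance matrix — is symmetric.
    """
    if variant not in VARIANTS:
        raise ParameterError(f"variant must be one of {VARIANTS}, got {variant!r}")
    P = _check_stochastic(P)
    pi = stationary_distribution(P)
    Q = hitting_probabilities(P)
    sq = np.sqrt(pi)
    if variant == "as_printed":
        T = sq[:, None] * sq[None, :] * Q
    else:
        T = (sq[:, None] / sq[None, :]) * Q
    np.fill_diagonal(T, 1.0)
    if np.any(T <= 0):
        raise NumericError(
            "non-positive entry in normalized hitting-time matrix; "
            "the chain is not irreducible (use alpha > 0)"
        )
    C = -np.log(T)
    if symmetrize:
        C = 0.5 * (C + C.T)
    np.fill_diagonal(C, 0.0)
    # similarity variant: tiny negatives can only arise from roundoff
    np.clip(C, 0.0, None, out=C)
    return CostMatrix(C, variant, bool(symmetrize))


def write_cost_matrix(cost: CostMatrix, edge_labels, path_or_buf) -> None:
    """Write C as a square CSV indexed by 'source->target' edge labels."""
    import pandas as pd

    pd.DataFrame(cost.C, index=list(edge_labels), columns=list(edge_labels)).to_csv(
        path_or_buf
    )
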