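"""Clustering samples in the Wasserstein geometry of CCC graphs.

Two complementary algorithms operate on the DW-OT geometry:

* **k-medoids** (PAM-style alternation) needs only the pairwise distance
  matrix and returns actual samples as cluster representatives.
* **k-barycenters**, an expectation-maximization scheme whose centroids are
  entropic (Sinkhorn) Wasserstein barycenters on the fixed STG support.
  The E-step assigns each sample to its nearest barycenter under the exact
  LP Wasserstein distance; the M-step recomputes each cluster's barycenter;
  iterations stop once assignments are stable and barycenters move less than
  a tolerance in L1. The whole EM is restarted from farthest-point seedings
  (100 restarts by default) and the restart with the lowest average
  per-cluster Wasserstein loss wins.

Barycenters are computed by iterative Bregman projections in the log domain,
so small regularization strengths do not underflow. Because the entropic
barycenter is a surrogate for the exact Wasserstein barycenter, a monotone
safeguard stops the EM the moment an M-step fails to reduce the exact loss,
keeping the per-restart loss trace non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.metrics import silhouette_samples

from .errors import NumericError, ParameterError, ValidationError
from .htd import CostMatrix
from .transport import normalize_signal, wasserstein

__all__ = [
    "Barycenter",
    "ClusteringResult",
    "k_medoids",
    "sinkhorn_barycenter",
    "seed_barycenters",
    "k_barycenters",
    "silhouette",
]


@dataclass(frozen=True)
class Barycenter:
    """A cluster centroid: a probability distribution over STG vertices."""

    mu: np.ndarray
    cluster_id: int


@dataclass(frozen=True)
class ClusteringResult:
    """Labels (1..k), representatives, and the average per-cluster loss.

    ``representatives`` holds medoid sample indices (k-medoids) or
    :class:`Barycenter` objects (k-barycenters). ``loss`` is the mean over
    clusters of the mean member-to-representative Wasserstein distance.
    ``loss_trace`` records the per-iteration loss of the winning restart.
    """

    labels: np.ndarray
    representatives: tuple
    loss: float
    n_restarts_used: int
    seed: int
    loss_trace: tuple[float, ...] = field(default_factory=tuple)
    restart_traces: tuple[tuple[float, ...], ...] = field(default_factory=tuple)

    @property
    def k(self) -> int:
        return len(self.representatives)


def _check_distance_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(np.diag(D), 0, atol=1e-10):
        raise ValidationError("distance matrix must have a zero diagonal")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValidationError("distance matrix must be symmetric")
    return D


def _per_cluster_loss(D_to_rep: np.ndarray, labels: np.ndarray, k: int) -> float:
    """Mean over clusters of mean member distance to the representative."""
    losses = []
    for j in range(k):
        members = labels == j
        if members.any():
            losses.append(D_to_rep[members, j].mean())
    return float(np.mean(losses))


def k_medoids(
    D: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 200,
    n_restarts: int = 10,
) -> ClusteringResult:
    """PAM-style k-medoids on a precomputed distance matrix.

    Alternates assignment to the nearest medoid with medoid updates (the
    in-cluster point minimizing summed distance) until labels stabilize.
    Ties break toward the lowest index; the best of ``n_restarts`` random
    initializations (by average per-cluster loss) is returned. Deterministic
    given ``seed``.
    """
    D = _check_distance_matrix(D)
    n = D.shape[0]
    if not (1 <= k <= n):
        raise ParameterError(f"k must be in [1, {n}], got {k}")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        medoids = np.sort(rng.choice(n, size=k, replace=False))
        labels = np.empty(n, dtype=int)
        for _ in range(max_iter):
            labels = np.argmin(D[:, medoids], axis=1)  # ties -> lowest index
            new_medoids = medoids.copy()
            for j in range(k):
                members = np.flatnonzero(labels == j)
                if members.size == 0:
                    # re-seed an empty cluster with the worst-served point
                    worst = int(np.argmax(D[np.arange(n), medoids[labels]]))
                    new_medoids[j] = worst
                    continue
                within = D[np.ix_(members, members)].sum(axis=1)
                new_medoids[j] = members[int(np.argmin(within))]
            if np.array_equal(new_medoids, medoids):
                break
            medoids = new_medoids
        labels = np.argmin(D[:, medoids], axis=1)
        loss = _per_cluster_loss(D[:, medoids], labels, k)
        if best is None or loss < best[0] - 1e-15:
            best = (loss, medoids, labels)
    loss, medoids, labels = best
    return ClusteringResult(labels + 1, tuple(int(m) for m in medoids), loss,
                            n_restarts, seed, (loss,))


def sinkhorn_barycenter(
    signals: np.ndarray,
    C: np.ndarray | CostMatrix,
    member_weights: np.ndarray | None = None,
    epsilon: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> np.ndarray:
    """Fixed-support entropic Wasserstein barycenter on the STG vertices.

    Iterative Bregman projections in the log domain: the barycenter is the
    weighted log-domain geometric mean of the column marginals of the
    partially-projected couplings. ``epsilon`` defaults to 1e-2 of the
    maximum ground cost. Converges when successive barycenters differ by
    less than ``tol`` in L1.
    """
    C = C.C if isinstance(C, CostMatrix) else np.asarray(C, dtype=float)
    S = np.atleast_2d(np.asarray(signals, dtype=float))
    m, E = S.shape
    if C.shape != (E, E):
        raise ValidationError("signals and cost matrix have inconsistent shapes")
    w = (np.full(m, 1.0 / m) if member_weights is None
         else np.asarray(member_weights, dtype=float))
    if len(w) != m or np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-8):
        raise ValidationError("member_weights must be non-negative and sum to 1")
    eps = epsilon if epsilon is not None else 1e-2 * max(C.max(), 1e-12)
    if eps <= 0:
        raise ParameterError("epsilon must be > 0")
    with np.errstate(divide="ignore"):
        logS = np.log(S)
    mlogK = -C / eps
    G = np.zeros((m, E))  # log v_s
    mu = np.full(E, 1.0 / E)
    for _ in range(max_iter):
        # row projection per input, then geometric-mean column projection
        F = logS - logsumexp(mlogK[None, :, :] + G[:, None, :], axis=2)
        logKTu = logsumexp(mlogK.T[None, :, :] + F[:, None, :], axis=2)
        log_mu = np.einsum("s,se->e", w, logKTu)
        log_mu -= logsumexp(log_mu)
        G = log_mu[None, :] - logKTu
        mu_new = np.exp(log_mu)
        if np.abs(mu_new - mu).sum() < tol:
            return mu_new
        mu = mu_new
    raise NumericError(
        f"barycenter did not converge in {max_iter} iterations "
        f"(last L1 step {np.abs(mu_new - mu).sum():.2e})"
    )


def seed_barycenters(
    signals: np.ndarray,
    C: np.ndarray | CostMatrix,
    k: int,
    seed: int = 0,
    mode: str = "farthest",
) -> np.ndarray:
    """Pick k samples as initial barycenters, spread out in Wasserstein space.

    The first pick is uniform at random (seeded); each subsequent pick
    maximizes (``mode="farthest"``) or samples proportionally to the squared
    (``mode="sampling"``, k-means++ style) Wasserstein distance to the
    nearest already-chosen sample. Returns the row indices of the chosen
    samples.
    """
    S = np.atleast_2d(np.asarray(signals, dtype=float))
    n = S.shape[0]
    if not (1 <= k <= n):
        raise ParameterError(f"k must be in [1, {n}], got {k}")
    if mode not in ("farthest", "sampling"):
        raise ParameterError(f"unknown seeding mode {mode!r}")
    rng = np.random.default_rng(seed)
    probs = np.stack([normalize_signal(S[i]) for i in range(n)])
    chosen = [int(rng.integers(n))]
    d_near = np.full(n, np.inf)
    while len(chosen) < k:
        last = chosen[-1]
        for i in range(n):
            if i in chosen:
                d_near[i] = 0.0
                continue
            d = wasserstein(probs[i], probs[last], C)[0]
            d_near[i] = min(d_near[i], d)
        if mode == "farthest":
            nxt = int(np.argmax(d_near))
        else:
            p = d_near**2
            if p.sum() <= 0:
                nxt = int(rng.integers(n))
            else:
                nxt = int(rng.choice(n, p=p / p.sum()))
        chosen.append(nxt)
    return np.array(chosen, dtype=int)


def k_barycenters(
    signals: np.ndarray,
    C: np.ndarray | CostMatrix,
    k: int,
    n_restarts: int = 100,
    seed: int = 0,
    epsilon: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 200,
    seeding: str = "farthest",
) -> ClusteringResult:
    """EM clustering with Wasserstein barycenters as centroids.

    Per restart: seed k barycenters from spread-out samples, then alternate
    an E-step (assign each sample to the nearest barycenter by exact LP
    Wasserstein distance, ties to the lowest cluster) and an M-step (Sinkhorn
    barycenter of the assigned signals) until labels are unchanged and
    barycenters move < ``tol`` in L1, or an M-step no longer lowers the exact
    loss. Empty clusters are re-seeded with the sample farthest from its own
    barycenter. Across restarts the solution with the lowest average
    per-cluster Wasserstein loss is returned; identical seeds reproduce
    identical results.
    """
    cost = C.C if isinstance(C, CostMatrix) else np.asarray(C, dtype=float)
    S = np.atleast_2d(np.asarray(signals, dtype=float))
    n, E = S.shape
    if not (1 <= k <= n):
        raise ParameterError(f"k must be in [1, {n}], got {k}")
    probs = np.stack([normalize_signal(S[i]) for i in range(n)])
    root = np.random.default_rng(seed)
    restart_seeds = root.integers(0, 2**31 - 1, size=n_restarts)
    best = None
    all_traces = []
    for r, rseed in enumerate(restart_seeds):
        init = seed_barycenters(probs, cost, k, seed=int(rseed), mode=seeding)
        mus = probs[init].copy()
        labels = np.full(n, -1)
        trace: list[float] = []
        state = None  # (labels, mus) snapshot matching the last traced loss
        for _ in range(max_iter):
            # E-step: nearest barycenter under the exact distance
            d = np.empty((n, k))
            for i in range(n):
                for j in range(k):
                    d[i, j] = wasserstein(probs[i], mus[j], cost)[0]
            new_labels = np.argmin(d, axis=1)
            for j in range(k):
                if not np.any(new_labels == j):
                    far = int(np.argmax(d[np.arange(n), new_labels]))
                    mus[j] = probs[far]
                    d[:, j] = [wasserstein(probs[i], mus[j], cost)[0]
                               for i in range(n)]
                    new_labels = np.argmin(d, axis=1)
            loss = _per_cluster_loss(d, new_labels, k)
            if trace and loss >= trace[-1] - 1e-12:
                # monotone safeguard: the entropic M-step stopped helping
                if loss < trace[-1]:
                    trace.append(loss)
                    state = (new_labels, mus.copy())
                break
            trace.append(loss)
            stable = np.array_equal(new_labels, labels)
            labels = new_labels
            state = (labels, mus.copy())
            # M-step
            new_mus = mus.copy()
            for j in range(k):
                members = probs[labels == j]
                new_mus[j] = sinkhorn_barycenter(members, cost, epsilon=epsilon)
            moved = np.abs(new_mus - mus).sum(axis=1).max()
            mus = new_mus
            if stable and moved < tol:
                break
        labels, mus = state
        all_traces.append(tuple(trace))
        if best is None or trace[-1] < best[0] - 1e-15:
            best = (trace[-1], labels, mus, tuple(trace))
    loss, labels, mus, trace = best
    reps = tuple(Barycenter(mus[j], j + 1) for j in range(k))
    return ClusteringResult(labels + 1, reps, loss, n_restarts, seed, trace,
                            tuple(all_traces))


def silhouette(D: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean and per-sample silhouette scores on a precomputed distance matrix.

    Singleton clusters get silhouette 0 (the standard convention).
    """
    D = _check_distance_matrix(D)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValidationError("silhouette requires at least 2 clusters")
    per_sample = silhouette_samples(D, labels, metric="precomputed")
    return float(per_sample.mean()), per_sample
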