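"""Scoring clusterings against known labels and sweeping cluster counts.

The adjusted Rand index (ARI) and raw Rand index compare two partitions by
pair agreement; ARI subtracts the expectation under the permutation null so
that random partitions score ~0. Both are computed here from the contingency
table directly (and cross-checked against scikit-learn in the test suite).
``sweep_k`` runs a clustering algorithm over a range of cluster counts and
seeds, mirroring a benchmark protocol that reports the ARI both at the true
number of classes and at the ARI-maximizing k.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError

__all__ = ["BenchmarkRecord", "adjusted_rand_index", "rand_index", "sweep_k",
           "write_benchmark"]


@dataclass(frozen=True)
class BenchmarkRecord:
    """One clustering evaluation: distance method x algorithm x k x seed."""

    method: str
    algorithm: str
    k: int
    ari: float
    rand: float
    seed: int


def _contingency(a, b):
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("label vectors must be 1-D and of equal length")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    n_ij = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(n_ij, (ai, bi), 1)
    return n_ij


def _comb2(x):
    return x * (x - 1) / 2.0


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected pair-agreement between two partitions, in [-1, 1].

    Computed from the contingency table as
    (sum_ij C(n_ij,2) - E) / (max - E), where E is the permutation-model
    expectation C(a,2)*C(b,2)/C(n,2) and max = (C(a,2)+C(b,2))/2.
    """
    n_ij = _contingency(labels_a, labels_b)
    n = n_ij.sum()
    sum_ij = _comb2(n_ij).sum()
    sum_a = _comb2(n_ij.sum(axis=1)).sum()
    sum_b = _comb2(n_ij.sum(axis=0)).sum()
    expected = sum_a * sum_b / _comb2(n)
    maximum = 0.5 * (sum_a + sum_b)
    if maximum == expected:  # both partitions trivial (all-one-cluster etc.)
        return 1.0
    return float((sum_ij - expected) / (maximum - expected))


def rand_index(labels_a, labels_b) -> float:
    """Raw fraction of sample pairs on which the two partitions agree."""
    n_ij = _contingency(labels_a, labels_b)
    n = n_ij.sum()
    total = _comb2(n)
    sum_ij = _comb2(n_ij).sum()
    sum_a = _comb2(n_ij.sum(axis=1)).sum()
    sum_b = _comb2(n_ij.sum(axis=0)).sum()
    # agreements = together in both + apart in both
    return float((total + 2 * sum_ij - sum_a - sum_b) / total)


def sweep_k(
    true_labels,
    algorithm: str = "k_medoids",
    k_min: int = 2,
    k_max: int = 7,
    seeds=(0,),
    D: np.ndarray | None = None,
    signals: np.ndarray | None = None,
    C: np.ndarray | None = None,
    method_tag: str = "dwot",
    n_restarts: int = 10,
) -> tuple[list[BenchmarkRecord], dict]:
    """Run a clustering algorithm for k in [k_min, k_max] across seeds.

    ``k_medoids`` needs the precomputed distance matrix ``D``;
    ``k_barycenters`` needs ``signals`` and the ground cost ``C``. Returns
    one record per (k, seed) plus a summary with the ARI-maximizing k and
    the mean ARI at k = number of true classes.
    """
    from . import clustering

    true_labels = np.asarray(true_labels)
    if k_min < 1 or k_max < k_min:
        raise ParameterError("invalid k range")
    if algorithm == "k_medoids":
        if D is None:
            raise ParameterError("k_medoids requires D")
    elif algorithm == "k_barycenters":
        if signals is None or C is None:
            raise ParameterError("k_barycenters requires signals and C")
    else:
        raise ParameterError(f"unknown algorithm {algorithm!r}")
    records = []
    for k in range(k_min, k_max + 1):
        for seed in seeds:
            if algorithm == "k_medoids":
                res = clustering.k_medoids(D, k, seed=seed)
            else:
                res = clustering.k_barycenters(signals, C, k, seed=seed,
                                               n_restarts=n_restarts)
            records.append(BenchmarkRecord(
                method_tag, algorithm, k,
                adjusted_rand_index(true_labels, res.labels),
                rand_index(true_labels, res.labels), seed))
    by_k = {k: np.mean([r.ari for r in records if r.k == k])
            for k in range(k_min, k_max + 1)}
    best_k = max(by_k, key=lambda k: (by_k[k], -k))
    k_true = len(np.unique(true_labels))
    summary = {
        "best_k": best_k,
        "best_ari": float(by_k[best_k]),
        "k_true": k_true,
        "ari_at_k_true": float(by_k[k_true]) if k_min <= k_true <= k_max else None,
    }
    return records, summary


def write_benchmark(records: list[BenchmarkRecord], path_or_buf) -> None:
    """Write benchmark records as a long-format CSV."""
    pd.DataFrame([asdict(r) for r in records]).to_csv(path_or_buf, index=False)
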