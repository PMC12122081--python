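import itertools

import numpy as np
import pytest

from cccot import (
    adjusted_rand_index,
    k_barycenters,
    k_medoids,
    silhouette,
    sinkhorn_barycenter,
    wasserstein,
)
from cccot.clustering import seed_barycenters
from cccot.errors import ParameterError, ValidationError


def block_distance_matrix(sizes, within=0.1, between=10.0, seed=0):
    labels = np.repeat(np.arange(len(sizes)), sizes)
    n = len(labels)
    rng = np.random.default_rng(seed)
    D = np.where(labels[:, None] == labels[None, :], within, between)
    D = D * (1 + 0.01 * rng.random((n, n)))
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    return D, labels


class TestKMedoids:
    def test_recovers_blocks_vs_exhaustive_search(self):
        D, truth = block_distance_matrix([2, 2])
        res = k_medoids(D, 2, seed=0)
        # exhaustive: the best 2-partition by summed within-cluster distance
        best, best_cost = None, np.inf
        for subset in itertools.combinations(range(4), 2):
            a = list(subset)
            b = [i for i in range(4) if i not in subset]
            if not b:
                continue
            cost = D[np.ix_(a, a)].sum() + D[np.ix_(b, b)].sum()
            if cost < best_cost:
                best, best_cost = (a, b), cost
        grouping = {tuple(sorted(np.flatnonzero(res.labels == c)))
                    for c in (1, 2)}
        assert grouping == {tuple(best[0]), tuple(best[1])}
        assert adjusted_rand_index(truth, res.labels) == 1.0

    def test_k_equals_n_zero_loss(self):
        D, _ = block_distance_matrix([2, 2])
        res = k_medoids(D, 4, seed=0)
        assert res.loss == pytest.approx(0.0)
        assert sorted(res.representatives) == [0, 1, 2, 3]

    def test_k_one_is_argmin_row_sum(self):
        D, _ = block_distance_matrix([3, 2], seed=3)
        res = k_medoids(D, 1, seed=0)
        assert res.representatives[0] == int(np.argmin(D.sum(axis=1)))

    def test_deterministic_given_seed(self):
        D, _ = block_distance_matrix([3, 3], seed=5)
        a, b = k_medoids(D, 2, seed=9), k_medoids(D, 2, seed=9)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.representatives == b.representatives

    def test_parameter_validation(self):
        D, _ = block_distance_matrix([2, 2])
        with pytest.raises(ParameterError):
            k_medoids(D, 5, seed=0)
        with pytest.raises(ValidationError):
            k_medoids(D[:3], 2, seed=0)


COST3 = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])


class TestSinkhornBarycenter:
    def test_identical_inputs_fixed_point(self):
        v = np.array([0.2, 0.5, 0.3])
        mu = sinkhorn_barycenter(np.tile(v, (4, 1)), COST3, tol=1e-10)
        np.testing.assert_allclose(mu, v, atol=1e-6)

    def test_degenerate_weight_selects_input(self):
        S = np.array([[0.8, 0.1, 0.1], [0.1, 0.1, 0.8]])
        mu = sinkhorn_barycenter(S, COST3, member_weights=np.array([1.0, 0.0]),
                                 tol=1e-10)
        np.testing.assert_allclose(mu, S[0], atol=1e-6)

    def test_swap_symmetry(self):
        # symmetric cost, inputs that are mirror images under reversing the
        # support: the barycenter must be invariant under the same reversal
        S = np.array([[0.7, 0.2, 0.1], [0.1, 0.2, 0.7]])
        mu = sinkhorn_barycenter(S, COST3, tol=1e-10)
        np.testing.assert_allclose(mu, mu[::-1], atol=1e-8)
        assert mu.sum() == pytest.approx(1.0, abs=1e-7)

    def test_weight_validation(self):
        with pytest.raises(ValidationError):
            sinkhorn_barycenter(np.array([[0.5, 0.5]]), np.zeros((2, 2)),
                                member_weights=np.array([0.7]))


class TestSeeding:
    def test_picks_are_distinct(self, small_geometry):
        esm, cost, _ = small_geometry
        idx = seed_barycenters(esm.values, cost.C, k=4, seed=0)
        assert len(set(idx.tolist())) == 4

    def test_farthest_mode_spans_groups(self, small_geometry):
        esm, cost, labels = small_geometry
        idx = seed_barycenters(esm.values, cost.C, k=2, seed=1)
        assert {labels[i] for i in idx} == {1, 2}

    def test_k_one_single_pick(self, small_geometry):
        esm, cost, _ = small_geometry
        assert len(seed_barycenters(esm.values, cost.C, k=1, seed=0)) == 1


class TestKBarycenters:
    def test_k_one_is_global_barycenter(self, small_geometry):
        esm, cost, _ = small_geometry
        res = k_barycenters(esm.values, cost, k=1, n_restarts=1, seed=0)
        assert np.all(res.labels == 1)
        probs = esm.values / esm.values.sum(axis=1, keepdims=True)
        mu = sinkhorn_barycenter(probs, cost)
        np.testing.assert_allclose(res.representatives[0].mu, mu, atol=1e-6)

    def test_recovers_two_groups(self, small_geometry):
        esm, cost, labels = small_geometry
        res = k_barycenters(esm.values, cost, k=2, n_restarts=3, seed=0)
        assert adjusted_rand_index(labels, res.labels) == 1.0

    def test_loss_trace_non_increasing(self, small_geometry):
        esm, cost, _ = small_geometry
        res = k_barycenters(esm.values, cost, k=2, n_restarts=3, seed=1)
        for trace in res.restart_traces:
            assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))
        assert res.loss == pytest.approx(min(t[-1] for t in res.restart_traces))

    def test_deterministic_given_seed(self, small_geometry):
        esm, cost, _ = small_geometry
        a = k_barycenters(esm.values, cost, k=2, n_restarts=2, seed=3)
        b = k_barycenters(esm.values, cost, k=2, n_restarts=2, seed=3)
        np.testing.assert_array_equal(a.labels, b.labels)
        for ra, rb in zip(a.representatives, b.representatives):
            np.testing.assert_array_equal(ra.mu, rb.mu)

    def test_agrees_with_k_medoids_on_separated_groups(self, small_geometry):
        from cccot import pairwise_distances

        esm, cost, labels = small_geometry
        D = pairwise_distances(esm.values, cost).D
        km = k_medoids(D, 2, seed=0)
        kb = k_barycenters(esm.values, cost, k=2, n_restarts=3, seed=0)
        assert adjusted_rand_index(km.labels, kb.labels) == 1.0


class TestSilhouette:
    def test_tight_far_blocks_high_score(self):
        D, labels = block_distance_matrix([5, 5])
        mean, per = silhouette(D, labels)
        assert mean > 0.9
        assert per.shape == (10,)

    def test_random_labels_near_zero(self):
        rng = np.random.default_rng(0)
        n = 40
        D = rng.random((n, n))
        D = 0.5 * (D + D.T)
        np.fill_diagonal(D, 0)
        means = [silhouette(D, rng.integers(0, 2, n))[0] for _ in range(10)]
        assert abs(np.mean(means)) < 0.1

    def test_singleton_cluster_scores_zero(self):
        D, _ = block_distance_matrix([2, 1])
        _, per = silhouette(D, np.array([0, 0, 1]))
        assert per[2] == 0.0

    def test_single_cluster_rejected(self):
        D, _ = block_distance_matrix([2, 2])
        with pytest.raises(ValidationError):
            silhouette(D, np.zeros(4, dtype=int))
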