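import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cccot import (
    corr_cost,
    normalize_signal,
    pairwise_distances,
    unbalanced_wasserstein,
    wasserstein,
)
from cccot.errors import ParameterError, ValidationError

from oracles import ot_dual_value

SWAP_COST = np.array([[0.0, 1.0], [1.0, 0.0]])


def _random_instance(E, rng):
    C = rng.random((E, E)) + 0.1
    np.fill_diagonal(C, 0.0)
    p = normalize_signal(rng.random(E) + 0.01)
    q = normalize_signal(rng.random(E) + 0.01)
    return p, q, C


class TestNormalizeSignal:
    def test_examples(self):
        np.testing.assert_allclose(normalize_signal([2.0, 2.0]), [0.5, 0.5])

    def test_idempotent_on_probability_vectors(self):
        p = np.array([0.2, 0.3, 0.5])
        np.testing.assert_allclose(normalize_signal(p), p)

    @given(st.lists(st.floats(0.01, 100), min_size=2, max_size=10))
    @settings(deadline=None, derandomize=True)
    def test_sums_to_one_and_proportional(self, w):
        w = np.asarray(w)
        p = normalize_signal(w)
        assert p.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(p * w.sum(), w)

    def test_rejects_zero_and_negative(self):
        with pytest.raises(ValidationError, match="all-zero"):
            normalize_signal(np.zeros(3))
        with pytest.raises(ValidationError):
            normalize_signal(np.array([-1.0, 2.0]))


class TestWasserstein:
    def test_identical_distributions_zero(self):
        p = np.array([0.3, 0.7])
        assert wasserstein(p, p, SWAP_COST)[0] == pytest.approx(0.0, abs=1e-12)

    def test_full_mass_swap(self):
        d, plan = wasserstein(np.array([1.0, 0.0]), np.array([0.0, 1.0]),
                              SWAP_COST)
        assert d == pytest.approx(1.0)
        np.testing.assert_allclose(plan.gamma, [[0, 1], [0, 0]], atol=1e-9)

    def test_partial_mass_move(self):
        # move 0.4 of mass at unit cost
        d, _ = wasserstein(np.array([0.7, 0.3]), np.array([0.3, 0.7]), SWAP_COST)
        assert d == pytest.approx(0.4)

    @pytest.mark.parametrize("E", [2, 3, 4])
    def test_exact_lp_matches_dual_oracle(self, E):
        rng = np.random.default_rng(E)
        for _ in range(10):
            p, q, C = _random_instance(E, rng)
            d, plan = wasserstein(p, q, C)
            assert d == pytest.approx(ot_dual_value(p, q, C), abs=1e-9)
            np.testing.assert_allclose(plan.gamma.sum(axis=1), p, atol=1e-9)
            np.testing.assert_allclose(plan.gamma.sum(axis=0), q, atol=1e-9)

    def test_sinkhorn_converges_to_lp_value(self):
        rng = np.random.default_rng(9)
        p, q, C = _random_instance(4, rng)
        exact = wasserstein(p, q, C)[0]
        errs = [abs(wasserstein(p, q, C, method="sinkhorn", epsilon=eps)[0] - exact)
                for eps in (0.5, 0.1, 0.02)]
        assert errs == sorted(errs, reverse=True)
        assert errs[-1] < 0.01

    def test_sinkhorn_plan_marginals(self):
        rng = np.random.default_rng(10)
        p, q, C = _random_instance(5, rng)
        _, plan = wasserstein(p, q, C, method="sinkhorn", epsilon=0.1)
        np.testing.assert_allclose(plan.gamma.sum(axis=1), p, atol=1e-7)
        np.testing.assert_allclose(plan.gamma.sum(axis=0), q, atol=1e-7)
        assert abs(plan.gamma.sum() - 1.0) < 1e-7

    def test_validation(self):
        with pytest.raises(ValidationError):
            wasserstein(np.array([0.5, 0.5]), np.array([1.0, 0.0, 0.0]),
                        SWAP_COST)
        with pytest.raises(ParameterError):
            wasserstein(np.array([0.5, 0.5]), np.array([0.5, 0.5]), SWAP_COST,
                        method="nope")


class TestPairwiseDistances:
    def test_identical_rows_all_zero(self):
        S = np.tile([1.0, 2.0, 3.0], (3, 1))
        C = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        D = pairwise_distances(S, C).D
        np.testing.assert_allclose(D, 0.0, atol=1e-10)

    def test_two_samples_symmetric(self):
        S = np.array([[1.0, 0.0], [0.0, 1.0]])
        dm = pairwise_distances(S, SWAP_COST)
        assert dm.D[0, 1] == dm.D[1, 0] == pytest.approx(1.0)
        assert dm.method == "dwot"

    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        S = rng.random((4, 3)) + 0.1
        C = rng.random((3, 3)) + 0.1
        np.fill_diagonal(C, 0)
        C = 0.5 * (C + C.T)
        D = pairwise_distances(S, C).D
        perm = np.array([2, 0, 3, 1])
        D_perm = pairwise_distances(S[perm], C).D
        np.testing.assert_allclose(D_perm, D[np.ix_(perm, perm)], atol=1e-9)


class TestUnbalanced:
    def test_equal_inputs_near_zero(self):
        # entropic smoothing leaves an O(epsilon)-scale residual at p = q
        p = np.array([0.2, 0.8])
        d, _ = unbalanced_wasserstein(p, p, SWAP_COST, rho=1.0)
        assert d == pytest.approx(0.0, abs=1e-4)

    def test_large_rho_approaches_balanced_sinkhorn(self):
        # the scaling iteration contracts at rate rho/(rho+eps), so a large
        # rho needs a matching iteration budget to resolve the limit
        rng = np.random.default_rng(5)
        p, q, C = _random_instance(4, rng)
        balanced = wasserstein(p, q, C, method="sinkhorn", epsilon=0.05)[0]
        ub = unbalanced_wasserstein(p, q, C, rho=1e3, epsilon=0.05,
                                    tol=5e-11, max_iter=300_000)[0]
        assert ub == pytest.approx(balanced, rel=0.01)

    def test_mass_creation_penalty_increases_with_rho(self):
        p = np.array([0.3, 0.7])
        q = 2 * p
        values = [unbalanced_wasserstein(p, q, SWAP_COST, rho=r, epsilon=0.05)[0]
                  for r in (0.1, 1.0, 10.0)]
        assert values[0] < values[1] < values[2]

    def test_rejects_bad_rho(self):
        with pytest.raises(ParameterError):
            unbalanced_wasserstein(np.ones(2), np.ones(2), SWAP_COST, rho=0.0)


class TestCorrCost:
    def test_duplicate_columns_cost_zero(self):
        S = np.array([[1.0, 1.0], [2.0, 2.0], [0.5, 0.5]])
        assert corr_cost(S).C[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_columns_cost_two(self):
        S = np.array([[1.0, -1.0], [2.0, -2.0], [0.0, 0.0]])
        assert corr_cost(S).C[0, 1] == pytest.approx(2.0)

    def test_matches_manual_pearson(self):
        rng = np.random.default_rng(6)
        S = rng.random((8, 5))
        C = corr_cost(S).C
        for i in range(5):
            for j in range(i + 1, 5):
                x, y = S[:, i] - S[:, i].mean(), S[:, j] - S[:, j].mean()
                r = (x @ y) / np.sqrt((x @ x) * (y @ y))
                assert C[i, j] == pytest.approx(1 - r, abs=1e-12)

    def test_zero_variance_convention(self):
        S = np.array([[1.0, 1.0], [1.0, 2.0], [1.0, 3.0]])
        C = corr_cost(S).C
        assert C[0, 1] == pytest.approx(1.0)  # undefined correlation -> 0
        assert C[0, 0] == 0.0

    def test_single_sample_rejected(self):
        with pytest.raises(ValidationError):
            corr_cost(np.array([[1.0, 2.0]]))
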