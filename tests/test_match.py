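"""SVD projection, cross-modal distances, and linear assignment."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from crossfuse.exceptions import DataError, ParameterError
from crossfuse.match import (
    batched_match,
    cross_distance,
    initial_match,
    linear_assignment,
    svd_denoise,
    svd_project,
)


def brute_force_assignment(d: np.ndarray) -> float:
    """Enumerate every feasible assignment; return the minimum objective."""
    n_y, n_z = d.shape
    best = np.inf
    if n_y <= n_z:
        for cols in itertools.permutations(range(n_z), n_y):
            best = min(best, sum(d[i, c] for i, c in enumerate(cols)))
    else:
        for rows in itertools.permutations(range(n_y), n_z):
            best = min(best, sum(d[r, j] for j, r in enumerate(rows)))
    return best


class TestSvdProject:
    def test_full_rank_reconstruction(self, rng):
        a = rng.standard_normal((8, 4))
        r = 4
        centered = a - a.mean(axis=0)
        scores = svd_project(a, r)
        # scores are a rotation of the centered data: distances preserved
        np.testing.assert_allclose(
            cdist(scores, scores), cdist(centered, centered), atol=1e-10
        )

    def test_rank1_scores_reproduce_distances(self, rng):
        u = rng.standard_normal((10, 1))
        a = u @ rng.standard_normal((1, 5))
        scores = svd_project(a, 1)
        centered = a - a.mean(axis=0)
        np.testing.assert_allclose(
            cdist(scores, scores), cdist(centered, centered), atol=1e-10
        )

    def test_rotation_invariance_of_score_distances(self, rng):
        a = rng.standard_normal((12, 5))
        q, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        s1, s2 = svd_project(a, 3), svd_project(a @ q, 3)
        np.testing.assert_allclose(cdist(s1, s1), cdist(s2, s2), atol=1e-10)

    def test_deterministic_sign(self, rng):
        a = rng.standard_normal((9, 4))
        np.testing.assert_array_equal(svd_project(a, 3), svd_project(a.copy(), 3))

    def test_r_too_large(self, rng):
        with pytest.raises(ParameterError):
            svd_project(rng.standard_normal((3, 2)), 3)


def test_svd_denoise_full_rank_is_identity(rng):
    a = rng.standard_normal((7, 4))
    np.testing.assert_allclose(svd_denoise(a, 4), a, atol=1e-12)


def test_svd_denoise_recovers_low_rank_signal(rng):
    signal = rng.standard_normal((40, 2)) @ rng.standard_normal((2, 6))
    noisy = signal + 0.01 * rng.standard_normal((40, 6))
    np.testing.assert_allclose(svd_denoise(noisy, 2), signal, atol=0.05)


class TestCrossDistance:
    def test_identical_rows_distance_zero(self):
        a = np.array([[1.0, 2.0, 3.0]])
        assert cross_distance(a, a.copy()).values[0, 0] == pytest.approx(0, abs=1e-12)

    def test_anticorrelated_rows_distance_two(self):
        a = np.array([[1.0, 2.0, 3.0]])
        b = -a
        assert cross_distance(a, b).values[0, 0] == pytest.approx(2, abs=1e-12)

    def test_hand_computed_pearson(self):
        a = np.array([[1.0, 2.0]])
        b = np.array([[2.0, 4.0], [2.0, 1.0]])
        np.testing.assert_allclose(cross_distance(a, b).values, [[0.0, 2.0]], atol=1e-12)

    def test_correlation_needs_two_columns(self):
        with pytest.raises(ParameterError):
            cross_distance(np.ones((2, 1)), np.ones((3, 1)), "correlation")

    def test_correlation_range(self, rng):
        d = cross_distance(rng.standard_normal((10, 5)), rng.standard_normal((8, 5)))
        assert d.values.min() >= 0 and d.values.max() <= 2


class TestLinearAssignment:
    def test_diagonal_optimum(self):
        t = linear_assignment(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert t.pairs() == [(0, 0), (1, 1)] and t.objective == 0

    def test_single_entry(self):
        t = linear_assignment(np.array([[5.0]]))
        assert t.pairs() == [(0, 0)] and t.objective == 5

    def test_rectangular_hand_enumerated(self):
        t = linear_assignment(np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 1.0]]))
        assert set(t.pairs()) == {(0, 0), (1, 2)} and t.objective == 2

    def test_empty_raises(self):
        with pytest.raises(DataError):
            linear_assignment(np.empty((0, 0)))

    def test_objective_matches_brute_force(self, rng):
        for _ in range(100):
            shape = rng.integers(1, 7, size=2)
            d = rng.random(shape)
            assert linear_assignment(d).objective == pytest.approx(
                brute_force_assignment(d), abs=1e-12
            )

    def test_constant_shift_leaves_pairs_unchanged(self, rng):
        d = rng.random((5, 5))
        t1 = linear_assignment(d)
        t2 = linear_assignment(d + 3.7)
        assert t1.pairs() == t2.pairs()
        assert t2.objective == pytest.approx(t1.objective + 5 * 3.7, rel=1e-12)

    def test_pair_count_is_n_min(self, rng):
        for ny, nz in [(3, 8), (8, 3), (5, 5)]:
            assert len(linear_assignment(rng.random((ny, nz)))) == min(ny, nz)


class TestInitialMatch:
    def test_row_permutation_recovered(self, rng):
        y = rng.standard_normal((12, 6))
        perm = rng.permutation(12)
        t = initial_match(y, y[perm], svd_y=6, svd_z=6)
        recovered = {(int(a), int(b)) for a, b in t.pairs()}
        assert recovered == {(int(perm[j]), int(j)) for j in range(12)}

    def test_two_cluster_pairs_stay_within_cluster(self, rng):
        centers = np.array([[0.0] * 4, [8.0] * 4])
        labels = np.repeat([0, 1], 5)
        y = centers[labels] + 0.1 * rng.standard_normal((10, 4))
        z = centers[labels] + 0.1 * rng.standard_normal((10, 4))
        t = initial_match(y, z, metric="euclidean")
        assert np.array_equal(labels[t.idx_a], labels[t.idx_b])

    def test_pair_count_contract(self, rng):
        t = initial_match(rng.standard_normal((5, 4)), rng.standard_normal((8, 4)))
        assert len(t) == 5


class TestBatchedMatch:
    def test_single_batch_equals_unbatched(self, rng):
        y, z = rng.standard_normal((10, 5)), rng.standard_normal((7, 5))
        t1 = initial_match(y, z)
        t2 = batched_match(y, z, 100, np.random.default_rng(0))
        assert t1.pairs() == t2.pairs()

    def test_batches_cover_all_larger_side_cells(self, rng):
        y = rng.standard_normal((20, 5))
        perm = rng.permutation(20)
        t = batched_match(y[perm], y, 7, np.random.default_rng(1))
        assert set(t.idx_a.tolist()) == set(range(20))

    def test_seeded_determinism(self, rng):
        y, z = rng.standard_normal((15, 4)), rng.standard_normal((9, 4))
        t1 = batched_match(y, z, 5, np.random.default_rng(3))
        t2 = batched_match(y, z, 5, np.random.default_rng(3))
        assert t1.pairs() == t2.pairs()
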