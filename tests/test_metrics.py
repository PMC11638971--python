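"""Evaluation criteria: matching accuracy, FOSCTTM/FOSKNN, silhouette/ARI F1."""

import numpy as np
import pytest

from crossfuse.datatypes import MatchTable
from crossfuse.exceptions import DataError, ParameterError
from crossfuse.metrics import (
    ari_f1,
    foscttm,
    fosknn,
    knn_match_from_embedding,
    matching_accuracy,
    silhouette_f1,
)


def _table(pairs):
    a, b = zip(*pairs)
    return MatchTable(np.array(a), np.array(b), np.zeros(len(pairs)))


def foscttm_double_loop(ey, ez):
    n = len(ey)
    total = 0.0
    for i in range(n):
        ny = sum(
            np.linalg.norm(ey[i] - ez[j]) < np.linalg.norm(ey[i] - ez[i])
            for j in range(n)
        )
        nz = sum(
            np.linalg.norm(ey[j] - ez[i]) < np.linalg.norm(ey[i] - ez[i])
            for j in range(n)
        )
        total += ny / n + nz / n
    return total / (2 * n)


class TestMatchingAccuracy:
    def test_all_same_label(self):
        t = _table([(0, 0), (1, 1)])
        assert matching_accuracy(t, ["T", "B"], ["T", "B"]) == 1.0

    def test_half_same_label(self):
        t = _table([(0, 0), (1, 1), (2, 2), (3, 3)])
        assert matching_accuracy(t, list("TBTB"), list("TTTT")) == 0.5

    def test_empty_is_error_not_zero(self):
        t = MatchTable(np.empty(0, int), np.empty(0, int), np.empty(0))
        with pytest.raises(DataError):
            matching_accuracy(t, [], [])

    def test_missing_label_names_index(self):
        t = _table([(0, 3)])
        with pytest.raises(DataError, match="3"):
            matching_accuracy(t, ["T"], ["T", "B"])


class TestKnnMatch:
    def test_identical_embeddings_identity_pairing(self, rng):
        e = rng.standard_normal((8, 4))
        t = knn_match_from_embedding(e, e.copy())
        assert t.pairs() == [(i, i) for i in range(8)]

    def test_single_query_argmin(self):
        ey = np.array([[1.0, 0.0, 0.5]])
        ez = np.array([[0.0, 1.0, 0.5], [1.0, 0.1, 0.45], [-1.0, 0.0, -0.5]])
        t = knn_match_from_embedding(ey, ez)
        assert t.pairs() == [(0, 1)]

    def test_positive_row_scaling_invariance(self, rng):
        ey, ez = rng.standard_normal((6, 3)), rng.standard_normal((6, 3))
        t1 = knn_match_from_embedding(ey, ez)
        t2 = knn_match_from_embedding(ey, ez * rng.uniform(0.5, 3, size=(6, 1)))
        assert t1.pairs() == t2.pairs()


class TestFoscttm:
    def test_perfect_alignment_zero(self, rng):
        e = rng.standard_normal((10, 3))
        assert foscttm(e, e.copy()) == 0.0

    def test_n2_swapped_half(self):
        ey = np.array([[0.0], [1.0]])
        ez = np.array([[1.0], [0.0]])
        assert foscttm(ey, ez) == 0.5

    def test_random_embeddings_near_half(self):
        rng = np.random.default_rng(0)
        ey, ez = rng.standard_normal((500, 5)), rng.standard_normal((500, 5))
        assert abs(foscttm(ey, ez) - 0.5) < 0.05

    def test_matches_double_loop_oracle(self, rng):
        for n in (5, 17, 30):
            ey = rng.standard_normal((n, 3))
            ez = ey + 0.5 * rng.standard_normal((n, 3))
            assert foscttm(ey, ez) == pytest.approx(foscttm_double_loop(ey, ez), abs=1e-12)

    def test_rigid_motion_invariance(self, rng):
        ey = rng.standard_normal((40, 3))
        ez = ey + 0.3 * rng.standard_normal((40, 3))
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        shift = rng.standard_normal(3)
        assert foscttm(ey @ q + shift, ez @ q + shift) == pytest.approx(
            foscttm(ey, ez), abs=1e-12
        )

    def test_unequal_sizes_error(self, rng):
        with pytest.raises(ParameterError, match="pairing"):
            foscttm(rng.standard_normal((4, 2)), rng.standard_normal((5, 2)))


class TestFosknn:
    def test_k_equals_n_is_one(self, rng):
        ey, ez = rng.standard_normal((9, 3)), rng.standard_normal((9, 3))
        assert fosknn(ey, ez, 9) == 1.0

    def test_identical_embeddings_k1(self, rng):
        e = rng.standard_normal((7, 3))
        assert fosknn(e, e.copy(), 1) == 1.0

    def test_n2_swapped_k1_zero(self):
        assert fosknn(np.array([[0.0], [1.0]]), np.array([[1.0], [0.0]]), 1) == 0.0

    def test_nondecreasing_in_k(self, rng):
        ey = rng.standard_normal((30, 4))
        ez = ey + rng.standard_normal((30, 4))
        vals = [fosknn(ey, ez, k) for k in (1, 2, 5, 10, 20, 30)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestCompositeF1:
    def test_harmonic_mean_arithmetic(self):
        # direct formula checks via the private helper behavior
        from crossfuse.metrics import _f1

        assert _f1(0.5, 0.5) == 0.5
        assert _f1(1.0, 0.0) == 0.0
        assert _f1(0.8, 0.4) == pytest.approx(0.533333333, abs=1e-8)
        assert _f1(0.0, 0.0) == 0.0

    def test_silhouette_f1_good_integration_beats_bad(self, rng):
        # two cell types, both modalities mixed within each type
        centers = np.array([[0.0, 0.0], [6.0, 6.0]])
        ct = np.array(["A"] * 100 + ["B"] * 100)
        emb_good = centers[(np.arange(200) >= 100).astype(int)] + 0.5 * rng.standard_normal((200, 2))
        modality = np.array(["m1", "m2"] * 100)
        # bad: modalities separated instead of cell types
        emb_bad = centers[(np.arange(200) % 2)] + 0.5 * rng.standard_normal((200, 2))
        assert silhouette_f1(emb_good, modality, ct) > silhouette_f1(emb_bad, modality, ct)

    def test_silhouette_single_label_errors(self, rng):
        e = rng.standard_normal((10, 2))
        with pytest.raises(ParameterError):
            silhouette_f1(e, ["m"] * 10, ["A"] * 5 + ["B"] * 5)

    def test_ari_clusters_equal_celltypes(self, rng):
        centers = np.array([[0.0, 0.0], [10.0, 10.0]])
        ct = np.array(["A"] * 50 + ["B"] * 50)
        emb = centers[(np.arange(100) >= 50).astype(int)] + 0.2 * rng.standard_normal((100, 2))
        modality = np.array(["m1", "m2"] * 50)
        v = ari_f1(emb, modality, ct, seed=0)
        assert v > 0.95  # ari_clust = 1, ari_mix ~ 1

    def test_ari_clusters_equal_modality_is_zero(self, rng):
        centers = np.array([[0.0, 0.0], [10.0, 10.0]])
        modality = np.array(["m1"] * 50 + ["m2"] * 50)
        ct = np.array(["A", "B"] * 50)
        emb = centers[(np.arange(100) >= 50).astype(int)] + 0.2 * rng.standard_normal((100, 2))
        assert ari_f1(emb, modality, ct, seed=0) == 0.0
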