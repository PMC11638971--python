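"""PCA, two-view CCA against an eigen-oracle, and generalized CCA."""

import numpy as np
import pytest
from scipy import linalg
from scipy.spatial.distance import cdist

from crossfuse.embed import cc_scores, cca_fit, gcca_fit, pca_fit, pca_reduce
from crossfuse.exceptions import ParameterError


def cca_eigen_oracle(x: np.ndarray, z: np.ndarray, r: int) -> np.ndarray:
    """Canonical correlations from the generalized eigenproblem

        [[0, Cxz], [Czx, 0]] v = rho [[Cxx, 0], [0, Czz]] v,

    solved independently of the SVD-whitening route used by cca_fit."""
    n = x.shape[0]
    xc = x - x.mean(axis=0)
    zc = z - z.mean(axis=0)
    cxx = xc.T @ xc / (n - 1)
    czz = zc.T @ zc / (n - 1)
    cxz = xc.T @ zc / (n - 1)
    p, q = cxx.shape[0], czz.shape[0]
    a = np.zeros((p + q, p + q))
    a[:p, p:] = cxz
    a[p:, :p] = cxz.T
    b = linalg.block_diag(cxx, czz)
    w = linalg.eigh(a, b, eigvals_only=True)
    return np.sort(w)[::-1][:r]


class TestPCA:
    def test_line_in_3d_preserves_distances_with_r1(self, rng):
        t = rng.standard_normal((15, 1))
        x = t @ np.array([[1.0, 2.0, -1.0]])
        s = pca_reduce(x, 1)
        np.testing.assert_allclose(cdist(s, s), cdist(x, x), atol=1e-10)

    def test_full_dimension_is_isometry(self, rng):
        x = rng.standard_normal((20, 4))
        s = pca_reduce(x, 4)
        np.testing.assert_allclose(cdist(s, s), cdist(x, x), atol=1e-10)

    def test_duplicated_rows_have_duplicated_scores(self, rng):
        x = rng.standard_normal((6, 3))
        x[3] = x[0]
        s = pca_reduce(x, 2)
        np.testing.assert_allclose(s[3], s[0], atol=1e-12)

    def test_out_of_sample_transform_matches_training_scores(self, rng):
        x = rng.standard_normal((12, 5))
        model = pca_fit(x, 3)
        np.testing.assert_allclose(model.transform(x), model.scores, atol=1e-10)

    def test_r_too_large(self, rng):
        with pytest.raises(ParameterError):
            pca_reduce(rng.standard_normal((4, 3)), 4)


class TestCCA:
    def test_identical_views_full_correlation(self, rng):
        x = rng.standard_normal((50, 4))
        m = cca_fit(x, x.copy(), 4, ridge=0.0)
        np.testing.assert_allclose(m.correlations, 1.0, atol=1e-8)

    def test_orthogonal_rotation_full_correlation(self, rng):
        x = rng.standard_normal((60, 5))
        q, _ = np.linalg.qr(rng.standard_normal((5, 5)))
        m = cca_fit(x, x @ q, 5, ridge=0.0)
        np.testing.assert_allclose(m.correlations, 1.0, atol=1e-8)

    def test_independent_views_low_leading_correlation(self, rng):
        x = rng.standard_normal((2000, 2))
        z = rng.standard_normal((2000, 2))
        m = cca_fit(x, z, 2, ridge=0.0)
        assert m.correlations[0] < 0.1

    def test_matches_eigen_oracle_on_random_instances(self, rng):
        for _ in range(50):
            p, q = rng.integers(2, 11, size=2)
            r = int(min(p, q))
            x = rng.standard_normal((200, p))
            z = 0.5 * x[:, : min(p, q)] @ rng.standard_normal((min(p, q), q)) \
                + rng.standard_normal((200, q))
            m = cca_fit(x, z, r, ridge=0.0)
            np.testing.assert_allclose(
                m.correlations, cca_eigen_oracle(x, z, r), atol=1e-8
            )

    def test_correlations_nonincreasing_and_in_range(self, rng):
        m = cca_fit(rng.standard_normal((80, 6)), rng.standard_normal((80, 5)), 5)
        assert np.all(np.diff(m.correlations) <= 1e-12)
        assert np.all((m.correlations >= 0) & (m.correlations <= 1))

    def test_row_permutation_invariance(self, rng):
        x, z = rng.standard_normal((40, 4)), rng.standard_normal((40, 3))
        perm = rng.permutation(40)
        m1 = cca_fit(x, z, 3, ridge=0.0)
        m2 = cca_fit(x[perm], z[perm], 3, ridge=0.0)
        np.testing.assert_allclose(m1.correlations, m2.correlations, atol=1e-10)

    def test_singular_covariance_without_ridge_raises(self, rng):
        x = rng.standard_normal((20, 3))
        x[:, 2] = x[:, 0]  # exactly collinear
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            cca_fit(x, rng.standard_normal((20, 2)), 2, ridge=0.0)

    def test_ridge_limit_recovers_classical(self, rng):
        x, z = rng.standard_normal((100, 4)), rng.standard_normal((100, 4))
        c0 = cca_fit(x, z, 3, ridge=0.0).correlations
        c1 = cca_fit(x, z, 3, ridge=1e-10).correlations
        np.testing.assert_allclose(c0, c1, atol=1e-6)


class TestCCScores:
    def test_subset_consistency(self, rng):
        x, z = rng.standard_normal((30, 4)), rng.standard_normal((30, 3))
        m = cca_fit(x, z, 2)
        all_scores = cc_scores(m, x, "y")
        np.testing.assert_allclose(cc_scores(m, x[:5], "y"), all_scores[:5], atol=1e-12)

    def test_perfect_pivots_give_equal_scores(self, rng):
        x = rng.standard_normal((40, 4))
        m = cca_fit(x, x.copy(), 3, ridge=0.0)
        np.testing.assert_allclose(
            cc_scores(m, x, "y"), cc_scores(m, x, "z"), atol=1e-8
        )

    def test_dimension_mismatch(self, rng):
        m = cca_fit(rng.standard_normal((10, 3)), rng.standard_normal((10, 3)), 2)
        with pytest.raises(ParameterError):
            cc_scores(m, rng.standard_normal((5, 4)), "y")


class TestGCCA:
    def test_three_identical_views_fully_correlated(self, rng):
        x = rng.standard_normal((60, 4))
        g = gcca_fit([x, x.copy(), x.copy()], 3, ridge=0.0)
        np.testing.assert_allclose(g.correlations, 1.0, atol=1e-8)

    def test_duplicated_view_matches_two_view_cca(self, rng):
        lat = rng.standard_normal((300, 3))
        x = lat @ rng.standard_normal((3, 6)) + 0.5 * rng.standard_normal((300, 6))
        z = lat @ rng.standard_normal((3, 5)) + 0.5 * rng.standard_normal((300, 5))
        ref = cca_fit(x, z, 3, ridge=0.0)
        g = gcca_fit([x, z, z.copy()], 3, ridge=0.0)
        px = g.transform(x, 0)
        pz = g.transform(z, 1)
        got = np.array(
            [abs(np.corrcoef(px[:, j], pz[:, j])[0, 1]) for j in range(3)]
        )
        np.testing.assert_allclose(got, ref.correlations, atol=1e-6)

    def test_recovers_shared_1d_signal(self, rng):
        s = rng.standard_normal(500)
        views = [
            np.column_stack([s + 0.3 * rng.standard_normal(500),
                             rng.standard_normal(500)])
            for _ in range(3)
        ]
        g = gcca_fit(views, 1)
        proj = g.transform(views[0], 0)[:, 0]
        assert abs(np.corrcoef(proj, s)[0, 1]) > 0.9

    def test_rank_deficiency_warns_and_recovers(self, rng):
        x = rng.standard_normal((30, 3))
        x[:, 2] = x[:, 0]
        with pytest.warns(UserWarning, match="ridge"):
            g = gcca_fit([x, rng.standard_normal((30, 2)),
                          rng.standard_normal((30, 2))], 1, ridge=0.0)
        assert np.all(np.isfinite(g.loadings[0]))
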