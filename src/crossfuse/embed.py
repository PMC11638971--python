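"""Linear embeddings: PCA, canonical correlation analysis on matched pairs,
and generalized CCA for three row-aligned views.

CCA here is the classical two-view problem solved in closed form.  With
column-centered views ``X`` (n x p) and ``Z`` (n x q) and covariance blocks
``Cxx``, ``Czz``, ``Cxz``, the canonical directions are

    a_j = Cxx^{-1/2} u_j,   b_j = Czz^{-1/2} v_j,

where ``u_j, v_j`` are the leading singular vectors of the whitened
cross-covariance ``Cxx^{-1/2} Cxz Czz^{-1/2}`` and the singular values are
the canonical correlations.  A ridge term ``lambda * I`` is added to the
within-view covariances by default because the number of matched pairs can
approach the summed view dimensions; ``ridge = 0`` recovers classical CCA.

The three-view extension solves the multiset (SUMCOR/MAXVAR-style)
generalized eigenproblem ``C v = lambda B v`` with ``C`` the full stacked
covariance of the concatenated views and ``B`` its block-diagonal part, and
reports, per component, the mean pairwise Pearson correlation of the
projected views.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .exceptions import ParameterError

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------- PCA
@dataclass
class PCAModel:
    """Column-centered PCA with out-of-sample projection."""

    center: np.ndarray      # (p,)
    components: np.ndarray  # (p, r)
    scores: np.ndarray      # (n, r) training scores

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=np.float64) - self.center) @ self.components


def pca_fit(matrix: np.ndarray, r: int) -> PCAModel:
    matrix = np.asarray(matrix, dtype=np.float64)
    n, p = matrix.shape
    if not 1 <= r <= min(n - 1, p):
        raise ParameterError(f"r={r} must be in [1, min(n-1, p)={min(n - 1, p)}]")
    center = matrix.mean(axis=0)
    u, s, vh = np.linalg.svd(matrix - center, full_matrices=False)
    u, s, vh = u[:, :r], s[:r], vh[:r]
    for j in range(r):
        i = np.argmax(np.abs(vh[j]))
        if vh[j, i] < 0:
            vh[j] *= -1.0
            u[:, j] *= -1.0
    return PCAModel(center=center, components=vh.T, scores=u * s)


def pca_reduce(matrix: np.ndarray, r: int) -> np.ndarray:
    """Leading-r principal component scores of the column-centered matrix."""
    return pca_fit(matrix, r).scores


# --------------------------------------------------------------------- CCA
@dataclass
class CCAModel:
    """Two-view CCA loadings, canonical correlations and centering vectors."""

    loadings_y: np.ndarray      # (p_y, r_cc)
    loadings_z: np.ndarray      # (p_z, r_cc)
    correlations: np.ndarray    # (r_cc,) in [0, 1], nonincreasing
    center_y: np.ndarray
    center_z: np.ndarray


def _inv_sqrt_psd(c: np.ndarray, what: str) -> np.ndarray:
    w, v = linalg.eigh(c)
    tol = max(c.shape[0], 1) * np.finfo(float).eps * max(w.max(), 0.0)
    if w.min() <= tol:
        raise np.linalg.LinAlgError(
            f"{what} covariance is singular or indefinite; "
            "supply a positive ridge to regularize"
        )
    return (v / np.sqrt(w)) @ v.T


def default_ridge(c: np.ndarray) -> float:
    return 1e-3 * np.trace(c) / c.shape[0]


def cca_fit(
    x_pairs: np.ndarray,
    z_pairs: np.ndarray,
    r_cc: int,
    ridge: float | None = None,
) -> CCAModel:
    """Fit CCA on row-aligned matched pairs.

    ``ridge=None`` uses ``1e-3 * trace(C)/dim`` per view; pass ``0.0`` for
    classical (unregularized) CCA.
    """
    x = np.asarray(x_pairs, dtype=np.float64)
    z = np.asarray(z_pairs, dtype=np.float64)
    n = x.shape[0]
    if z.shape[0] != n:
        raise ParameterError("paired matrices must have the same number of rows")
    if n < 3:
        raise ParameterError(f"need at least 3 pairs, got {n}")
    if not 1 <= r_cc <= min(x.shape[1], z.shape[1], n - 1):
        raise ParameterError(
            f"r_cc={r_cc} must be in [1, min(p_y, p_z, n-1)="
            f"{min(x.shape[1], z.shape[1], n - 1)}]"
        )
    center_y = x.mean(axis=0)
    center_z = z.mean(axis=0)
    xc = x - center_y
    zc = z - center_z
    cxx = xc.T @ xc / (n - 1)
    czz = zc.T @ zc / (n - 1)
    cxz = xc.T @ zc / (n - 1)
    ry = default_ridge(cxx) if ridge is None else float(ridge)
    rz = default_ridge(czz) if ridge is None else float(ridge)
    wx = _inv_sqrt_psd(cxx + ry * np.eye(cxx.shape[0]), "Y-view")
    wz = _inv_sqrt_psd(czz + rz * np.eye(czz.shape[0]), "Z-view")
    u, s, vh = np.linalg.svd(wx @ cxz @ wz, full_matrices=False)
    loadings_y = wx @ u[:, :r_cc]
    loadings_z = wz @ vh[:r_cc].T
    # consistent sign: largest-|entry| of each y-loading positive, z flipped with it
    for j in range(r_cc):
        i = np.argmax(np.abs(loadings_y[:, j]))
        if loadings_y[i, j] < 0:
            loadings_y[:, j] *= -1.0
            loadings_z[:, j] *= -1.0
    correlations = np.clip(s[:r_cc], 0.0, 1.0)
    return CCAModel(loadings_y, loadings_z, correlations, center_y, center_z)


def cc_scores(model: CCAModel, x_all: np.ndarray, side: str = "y") -> np.ndarray:
    """Canonical correlation scores for every row (pivot or not) of a view."""
    x_all = np.asarray(x_all, dtype=np.float64)
    if side == "y":
        center, loadings = model.center_y, model.loadings_y
    elif side == "z":
        center, loadings = model.center_z, model.loadings_z
    else:
        raise ParameterError(f"side must be 'y' or 'z', got {side!r}")
    if x_all.shape[1] != loadings.shape[0]:
        raise ParameterError(
            f"matrix has {x_all.shape[1]} columns but model side {side!r} "
            f"expects {loadings.shape[0]}"
        )
    return (x_all - center) @ loadings


# -------------------------------------------------------------------- gCCA
@dataclass
class GCCAModel:
    """Generalized CCA over three row-aligned views."""

    loadings: list[np.ndarray]      # per view, (p_i, r)
    centers: list[np.ndarray]
    correlations: np.ndarray        # mean pairwise correlation per component

    def transform(self, x: np.ndarray, view: int) -> np.ndarray:
        return (np.asarray(x, dtype=np.float64) - self.centers[view]) @ self.loadings[view]


def gcca_fit(
    views: list[np.ndarray],
    r: int,
    ridge: float | None = None,
) -> GCCAModel:
    """Multiset CCA on row-aligned views via the stacked-covariance eigenproblem.

    Maximizes the sum of pairwise covariances of the projections under a
    total within-view variance constraint; per-view loadings are rescaled to
    unit projection variance afterwards.  Falls back to a default ridge with
    a warning if the within-view covariances are rank deficient.
    """
    views = [np.asarray(v, dtype=np.float64) for v in views]
    n = views[0].shape[0]
    if any(v.shape[0] != n for v in views):
        raise ParameterError("all views must have the same number of rows")
    dims = [v.shape[1] for v in views]
    if not 1 <= r <= min(dims + [n - 1]):
        raise ParameterError(f"r={r} must be in [1, {min(dims + [n - 1])}]")
    centers = [v.mean(axis=0) for v in views]
    centered = [v - c for v, c in zip(views, centers)]
    m = len(views)
    # stacked covariance C and block-diagonal B
    p_total = sum(dims)
    offs = np.concatenate([[0], np.cumsum(dims)])
    c_full = np.zeros((p_total, p_total))
    b_diag = np.zeros((p_total, p_total))
    for i in range(m):
        si = slice(offs[i], offs[i + 1])
        cii = centered[i].T @ centered[i] / (n - 1)
        lam = default_ridge(cii) if ridge is None else float(ridge)
        b_block = cii + lam * np.eye(dims[i])
        w = linalg.eigh(b_block, eigvals_only=True)
        if w.min() <= 0:
            fallback = default_ridge(cii) + abs(w.min())
            warnings.warn(
                "rank-deficient within-view covariance in gCCA; "
                f"adding ridge {fallback:.3g}",
                stacklevel=2,
            )
            b_block = cii + fallback * np.eye(dims[i])
        b_diag[si, si] = b_block
        c_full[si, si] = b_block
        for j in range(i + 1, m):
            sj = slice(offs[j], offs[j + 1])
            cij = centered[i].T @ centered[j] / (n - 1)
            c_full[si, sj] = cij
            c_full[sj, si] = cij.T
    w, v = linalg.eigh(c_full, b_diag)
    # largest eigenvalues = strongest shared structure
    order = np.argsort(w)[::-1][:r]
    vectors = v[:, order]
    # consistent sign across views: flip the whole stacked vector
    for j in range(r):
        i = np.argmax(np.abs(vectors[:, j]))
        if vectors[i, j] < 0:
            vectors[:, j] *= -1.0
    loadings = []
    for i in range(m):
        a = vectors[offs[i]:offs[i + 1], :].copy()
        proj = centered[i] @ a
        sd = proj.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        loadings.append(a / sd)
    # report mean pairwise correlation of projected training views
    projections = [centered[i] @ loadings[i] for i in range(m)]
    corrs = np.zeros(r)
    n_pairs = m * (m - 1) // 2
    for i in range(m):
        for j in range(i + 1, m):
            for comp in range(r):
                pi, pj = projections[i][:, comp], projections[j][:, comp]
                denom = pi.std() * pj.std()
                corrs[comp] += 0.0 if denom == 0 else float(
                    np.mean((pi - pi.mean()) * (pj - pj.mean())) / denom
                )
    corrs /= n_pairs
    return GCCAModel(loadings=loadings, centers=centers, correlations=corrs)
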