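"""Shared linear-algebra primitives for distance-based ordination.

A single Gower-centering routine backs PERMANOVA, dbRDA and classical
PCoA so that the three stages cannot drift apart numerically.
"""

from __future__ import annotations

import numpy as np

_RANK_TOL = 1e-10


def gower_center(distances: np.ndarray) -> np.ndarray:
    """Gower-centered inner-product matrix G = -1/2 * J D^2 J.

    ``distances`` is a symmetric dissimilarity matrix with zero diagonal.
    """
    d = np.asarray(distances, dtype=float)
    a = -0.5 * d ** 2
    n = d.shape[0]
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def hat_matrix(x: np.ndarray) -> np.ndarray:
    """Orthogonal projector onto the column space of ``x``.

    Rank-deficient (aliased) columns are handled by projecting onto the
    numerically identified column space via SVD.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0 or x.shape[1] == 0:
        return np.zeros((x.shape[0], x.shape[0]))
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > _RANK_TOL * max(s.max(), 1.0)))
    u = u[:, :rank]
    return u @ u.T


def matrix_rank(x: np.ndarray) -> int:
    if x.size == 0 or x.shape[1] == 0:
        return 0
    s = np.linalg.svd(x, compute_uv=False)
    return int(np.sum(s > _RANK_TOL * max(s.max(), 1.0)))


def pcoa_from_gower(g: np.ndarray):
    """Eigen-decompose a Gower-centered matrix into principal coordinates.

    Returns (coordinates, positive eigenvalues, negative eigenvalues).
    Negative eigenvalues (non-Euclidean distances) are dropped from the
    coordinates and reported separately; no additive-constant correction
    is applied.
    """
    g = (g + g.T) / 2.0
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = 1e-9 * max(abs(vals).max(), 1.0)
    pos = vals > tol
    neg_vals = vals[vals < -tol]
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    return coords, vals[pos], neg_vals
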