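"""PCCA+ spectral clustering of reversible transition matrices.

Implements the inner-simplex (ISA) construction of Deuflhard & Weber: the
rows of the leading-eigenvector matrix live (up to noise) inside a simplex
whose vertices correspond to the metastable sets; the vertices are located
by successive orthogonal projection and the membership matrix is the affine
map sending them to the unit vectors.  Small infeasibilities from estimator
noise are clipped and rows renormalized.
"""

from __future__ import annotations

import numpy as np

__all__ = ["pcca_memberships"]


def _inner_simplex_vertices(X: np.ndarray) -> np.ndarray:
    """Indices of m rows of X spanning the (m-1)-simplex."""
    n, m = X.shape
    index = np.zeros(m, dtype=np.int64)
    ortho = X.copy()
    index[0] = int(np.argmax(np.linalg.norm(ortho, axis=1)))
    ortho = ortho - ortho[index[0]]
    for j in range(1, m):
        dists = np.linalg.norm(ortho, axis=1)
        index[j] = int(np.argmax(dists))
        v = ortho[index[j]]
        nv = np.linalg.norm(v)
        if nv == 0:
            raise ValueError(
                "degenerate eigenvector geometry: fewer metastable "
                "directions than requested macrostates"
            )
        v = v / nv
        ortho = ortho - np.outer(ortho @ v, v)
    return index


def pcca_memberships(right_eigenvectors: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Membership matrix chi (n_micro x n_macro) from leading eigenvectors.

    ``right_eigenvectors`` holds the leading ``n_macro`` right eigenvectors
    of the reversible transition matrix as columns, the first being the
    stationary (constant) one.  Rows of chi sum to one with entries in
    [0, 1].
    """
    X = np.array(right_eigenvectors, dtype=np.float64)
    n, m = X.shape
    if m < 2:
        return np.ones((n, 1))
    if np.ptp(X[:, 0]) > 1e-8 * max(np.abs(X[:, 0]).max(), 1e-300):
        raise ValueError("first eigenvector is not constant")
    X[:, 0] = 1.0
    # scale the nontrivial columns for numerical balance
    for j in range(1, m):
        s = np.abs(X[:, j]).max()
        if s > 0:
            X[:, j] = X[:, j] / s
    idx = _inner_simplex_vertices(X)
    A = np.linalg.inv(X[idx])
    chi = X @ A
    chi = np.clip(chi, 0.0, 1.0)
    rows = chi.sum(axis=1)
    if np.any(rows <= 0):
        raise ValueError("PCCA+ produced an empty membership row")
    return chi / rows[:, None]
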