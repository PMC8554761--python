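"""Rototranslationally and strand-permutation invariant featurization.

Each frame of two L-base strands is reduced to the L x L matrix of
interstrand base-center distances, symmetrized under the strand-swap
permutation (entry (i, j) and (j, i) replaced by their mean), and mapped
through the reciprocal ``x -> 1/max(x, epsilon)`` to give an L*L-element
feature vector that resolves near-hybridized configurations sharply.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "interbase_distance_matrix",
    "distance_matrices",
    "symmetrized_reciprocal_features",
    "featurize_frames",
    "DEFAULT_EPSILON",
]

#: Distance floor (nm).  Templates never place base centers closer than
#: 0.3 nm, so the floor is inactive on valid data.
DEFAULT_EPSILON = 0.05


def interbase_distance_matrix(frame: np.ndarray) -> np.ndarray:
    """Distance matrix ``d[i, j]`` between strand-1 base i and strand-2 base j.

    ``frame`` has shape (2, L, 3) in nm; the result is (L, L) and is not in
    general symmetric.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 3 or frame.shape[0] != 2 or frame.shape[2] != 3:
        raise ValueError("frame must have shape (2, L, 3)")
    if not np.all(np.isfinite(frame)):
        raise ValueError("non-finite coordinates")
    diff = frame[0][:, None, :] - frame[1][None, :, :]
    return np.sqrt((diff * diff).sum(axis=-1))


def distance_matrices(frames: np.ndarray) -> np.ndarray:
    """Vectorized :func:`interbase_distance_matrix` over (n, 2, L, 3) frames."""
    frames = np.asarray(frames)
    if frames.ndim != 4 or frames.shape[1] != 2 or frames.shape[3] != 3:
        raise ValueError("frames must have shape (n, 2, L, 3)")
    diff = frames[:, 0, :, None, :].astype(np.float64) - \
        frames[:, 1, None, :, :].astype(np.float64)
    return np.sqrt((diff * diff).sum(axis=-1))


def symmetrized_reciprocal_features(
    d: np.ndarray, epsilon: float = DEFAULT_EPSILON
) -> np.ndarray:
    """Strand-swap symmetrize a distance matrix and take reciprocals.

    For i != j both (i, j) and (j, i) are replaced by their mean (the
    L*(L-1)/2 = 45 unordered off-diagonal pairs for L = 10); diagonal
    entries are self-invariant and left unchanged.  Every entry is then
    mapped to ``1/max(x, epsilon)`` and the matrix flattened row-major.

    Accepts a single (L, L) matrix or a stack (n, L, L); returns (L*L,) or
    (n, L*L) accordingly.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    d = np.asarray(d, dtype=float)
    single = d.ndim == 2
    if single:
        d = d[None]
    if d.ndim != 3 or d.shape[1] != d.shape[2]:
        raise ValueError("expected square distance matrices")
    if d.min() < 0:
        raise ValueError("negative distances")
    sym = 0.5 * (d + np.swapaxes(d, 1, 2))
    feats = 1.0 / np.maximum(sym, epsilon)
    n, L = feats.shape[0], feats.shape[1]
    out = feats.reshape(n, L * L)
    return out[0] if single else out


def featurize_frames(
    frames: np.ndarray,
    epsilon: float = DEFAULT_EPSILON,
    chunk: int = 200_000,
) -> np.ndarray:
    """Frames (n, 2, L, 3) -> features (n, L*L), processed in chunks."""
    frames = np.asarray(frames)
    n = frames.shape[0]
    L = frames.shape[2]
    out = np.empty((n, L * L), dtype=np.float32)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        d = distance_matrices(frames[lo:hi])
        out[lo:hi] = symmetrized_reciprocal_features(d, epsilon)
    return out
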