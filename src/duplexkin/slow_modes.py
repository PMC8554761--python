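"""Linear slow collective modes (tICA) and VAMP-2 kinetic-variance scoring.

The estimator solves the symmetrized time-lagged generalized eigenproblem

    C_tau v = lambda C_0 v,

with ``C_0`` the instantaneous covariance (ridge-regularized) and ``C_tau``
the average of the forward and reverse time-lagged covariances, which
enforces real eigenvalues on finite data from reversible dynamics.  The lag
is a physical choice and is never optimized against the score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

logger = logging.getLogger(__name__)

__all__ = [
    "SlowModeModel",
    "fit_linear_slow_modes",
    "vamp2_score",
    "cross_validated_vamp2",
]

DEFAULT_REG = 1e-6


def _as_series_list(features) -> list:
    if isinstance(features, np.ndarray) and features.ndim == 2:
        features = [features]
    out = [np.asarray(f, dtype=np.float64) for f in features]
    if not out:
        raise ValueError("no feature series provided")
    dim = out[0].shape[1]
    if any(f.ndim != 2 or f.shape[1] != dim for f in out):
        raise ValueError("all series must be 2-D with a common feature count")
    return out


def _lag_steps(lag: float, dt: float) -> int:
    steps = lag / dt
    if abs(steps - round(steps)) > 1e-9 or round(steps) < 1:
        raise ValueError(f"lag {lag} is not a positive multiple of dt {dt}")
    return int(round(steps))


def _lagged_covariances(series, steps, mean=None, keep=None):
    """Accumulate symmetrized instantaneous and time-lagged covariances."""
    dim = series[0].shape[1] if keep is None else int(keep.sum())
    c0 = np.zeros((dim, dim))
    ct = np.zeros((dim, dim))
    n = 0
    for s in series:
        if len(s) <= steps:
            continue
        x = s[:-steps]
        y = s[steps:]
        if keep is not None:
            x = x[:, keep]
            y = y[:, keep]
        if mean is not None:
            x = x - mean
            y = y - mean
        c0 += 0.5 * (x.T @ x + y.T @ y)
        ct += 0.5 * (x.T @ y + y.T @ x)
        n += len(x)
    if n == 0:
        raise ValueError("every series is shorter than the lag")
    return c0 / n, ct / n, n


def _pair_mean(series, steps, keep=None):
    dim = series[0].shape[1] if keep is None else int(keep.sum())
    total = np.zeros(dim)
    n = 0
    for s in series:
        if len(s) <= steps:
            continue
        x = s[:-steps] if keep is None else s[:-steps][:, keep]
        y = s[steps:] if keep is None else s[steps:][:, keep]
        total += x.sum(axis=0) + y.sum(axis=0)
        n += 2 * len(x)
    if n == 0:
        raise ValueError("every series is shorter than the lag")
    return total / n


@dataclass
class SlowModeModel:
    """Fitted linear slow-mode projection.

    ``components`` rows are projection vectors in the original feature
    space (zeros at dropped constant features); projected coordinates are
    ``(x - mean) @ components.T``.  Eigenvalues are the time-lagged
    autocorrelations of the projections, sorted descending.
    """

    lag: float
    dt_save: float
    mean: np.ndarray
    components: np.ndarray
    eigenvalues: np.ndarray
    n_modes: int
    kept_features: np.ndarray

    def transform(self, features) -> list:
        series = _as_series_list(features)
        return [(s - self.mean) @ self.components.T for s in series]


def fit_linear_slow_modes(
    features,
    lag: float,
    n_modes: int,
    reg: float = DEFAULT_REG,
    dt_save: float = 1.0,
) -> SlowModeModel:
    """Fit tICA at the given physical lag (``lag/dt_save`` frames).

    Zero-variance features are dropped with a warning.  Components are
    normalized to unit variance under the estimated instantaneous
    covariance, so eigenvalues are autocorrelations with |lambda| <= 1 up
    to estimator noise.
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    series = _as_series_list(features)
    steps = _lag_steps(lag, dt_save)
    dim = series[0].shape[1]

    # streaming variance for zero-variance screening (no concatenation)
    n_tot = sum(len(s) for s in series)
    mu = sum(s.sum(axis=0) for s in series) / n_tot
    var = sum(((s - mu) ** 2).sum(axis=0) for s in series) / n_tot
    keep = var > 0
    if not keep.any():
        raise ValueError("all features are constant")
    if not keep.all():
        logger.warning(
            "dropping %d zero-variance features", int((~keep).sum())
        )
    mean = _pair_mean(series, steps, keep=keep)
    c0, ct, _ = _lagged_covariances(series, steps, mean=mean, keep=keep)
    c0reg = c0 + reg * np.eye(c0.shape[0])
    evals, evecs = scipy.linalg.eigh(ct, c0reg)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    # normalize to unit instantaneous variance
    norms = np.sqrt(np.maximum(np.einsum("ij,jk,ki->i", evecs.T, c0reg, evecs), 1e-300))
    evecs = evecs / norms
    k = min(n_modes, evecs.shape[1])
    if k < n_modes:
        warnings.warn(
            f"requested {n_modes} modes but only {k} available", stacklevel=2
        )
    comps = np.zeros((k, dim))
    comps[:, keep] = evecs[:, :k].T
    full_mean = np.zeros(dim)
    full_mean[keep] = mean
    return SlowModeModel(
        lag=lag,
        dt_save=dt_save,
        mean=full_mean,
        components=comps,
        eigenvalues=evals[:k],
        n_modes=k,
        kept_features=keep,
    )


def vamp2_score(
    features, lag: float, k: int, reg: float = DEFAULT_REG, dt_save: float = 1.0
) -> float:
    """VAMP-2 score: sum of the squared leading transfer-operator eigenvalues.

    The stationary mode contributes exactly 1, so ``k = 1`` returns 1 on any
    stationary series and the score is non-decreasing in ``k``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return 1.0
    model = fit_linear_slow_modes(
        features, lag=lag, n_modes=k - 1, reg=reg, dt_save=dt_save
    )
    if model.n_modes < k - 1:
        warnings.warn(
            f"k={k} exceeds the feature rank; scoring over "
            f"{model.n_modes + 1} modes", stacklevel=2
        )
    lams = np.clip(model.eigenvalues, 0.0, 1.0)
    return 1.0 + float((lams ** 2).sum())


def _score_on(model: SlowModeModel, series, steps: int) -> float:
    """Score held-out series with a fitted projection.

    The held-out eigenvalue estimate for each mode is its symmetrized
    time-lagged autocorrelation on the validation data.
    """
    proj = model.transform(series)
    lams = []
    for m in range(model.n_modes):
        num = 0.0
        den = 0.0
        npairs = 0
        for p in proj:
            if len(p) <= steps:
                continue
            x, y = p[:-steps, m], p[steps:, m]
            mu = 0.5 * (x.mean() + y.mean())
            num += ((x - mu) * (y - mu)).sum()
            den += 0.5 * (((x - mu) ** 2).sum() + ((y - mu) ** 2).sum())
            npairs += len(x)
        if npairs == 0:
            raise ValueError("validation series shorter than the lag")
        lams.append(num / max(den, 1e-300))
    lams = np.clip(np.array(lams), 0.0, 1.0)
    return 1.0 + float((lams ** 2).sum())


def cross_validated_vamp2(
    features,
    lag: float,
    k: int,
    n_folds: int,
    seed: int,
    reg: float = DEFAULT_REG,
    dt_save: float = 1.0,
):
    """Trajectory-level k-fold cross-validated VAMP-2 scores.

    Whole series (never individual frames) are partitioned into folds;
    returns ``(train_scores, validation_scores)`` lists of length
    ``n_folds``.  Deterministic given the seed.
    """
    series = _as_series_list(features)
    if len(series) < n_folds:
        raise ValueError(
            f"need at least n_folds={n_folds} series, got {len(series)}"
        )
    steps = _lag_steps(lag, dt_save)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(series))
    folds = np.array_split(perm, n_folds)
    train_scores, val_scores = [], []
    for fold in folds:
        val_idx = set(fold.tolist())
        train = [s for i, s in enumerate(series) if i not in val_idx]
        val = [series[i] for i in sorted(val_idx)]
        if k == 1:
            train_scores.append(1.0)
            val_scores.append(1.0)
            continue
        model = fit_linear_slow_modes(
            train, lag=lag, n_modes=k - 1, reg=reg, dt_save=dt_save
        )
        train_scores.append(_score_on(model, train, steps))
        val_scores.append(_score_on(model, val, steps))
    return train_scores, val_scores
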