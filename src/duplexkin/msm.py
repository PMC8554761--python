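"""Markov state model estimation on clustered embeddings.

Implements sliding-window transition counting, ergodic trimming to the
largest strongly connected set, reversible maximum-likelihood transition
matrix estimation by the standard self-consistent fixed-point iteration,
implied timescales, the Chapman-Kolmogorov test, PCCA+ coarse-graining into
macrostates, a spectral-gap rule for the macrostate count, and trajectory
bootstrap uncertainties.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse.csgraph
from sklearn.cluster import KMeans

from ._pcca import pcca_memberships

logger = logging.getLogger(__name__)

__all__ = [
    "MicrostateAssignment",
    "ReversibleMSM",
    "MacrostateModel",
    "cluster_microstates",
    "count_transitions",
    "reversible_mle",
    "estimate_reversible_msm",
    "ck_test",
    "pcca_coarse_grain",
    "select_n_macrostates",
    "bootstrap_uncertainty",
]


def _as_label_list(labels) -> list:
    if isinstance(labels, np.ndarray) and labels.ndim == 1:
        labels = [labels]
    out = [np.asarray(t, dtype=np.int64) for t in labels]
    if not out:
        raise ValueError("no trajectories provided")
    return out


@dataclass
class MicrostateAssignment:
    """Per-frame microstate ids for each trajectory plus cluster centers."""

    labels: list
    centers: np.ndarray
    k: int
    seed: int
    dt_save: float = 1.0

    def __post_init__(self) -> None:
        self.labels = _as_label_list(self.labels)
        for t in self.labels:
            if t.min() < 0 or t.max() >= self.k:
                raise ValueError("labels outside [0, k)")
        if not np.all(np.isfinite(self.centers)):
            raise ValueError("non-finite centers")


def cluster_microstates(
    embedding, k: int, seed: int, dt_save: float = 1.0, max_iter: int = 300
) -> MicrostateAssignment:
    """Seeded k-means clustering of projected trajectories.

    ``embedding`` is a single (n, d) array or a list of them (one per
    trajectory).  Deterministic for a fixed seed.
    """
    if isinstance(embedding, np.ndarray) and embedding.ndim == 2:
        embedding = [embedding]
    series = [np.asarray(e, dtype=np.float64) for e in embedding]
    x = np.concatenate(series, axis=0)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(x) < k:
        raise ValueError("fewer frames than clusters")
    n_distinct = len(np.unique(x, axis=0))
    if n_distinct < k:
        raise ValueError(
            f"k={k} exceeds the number of distinct points ({n_distinct})"
        )
    km = KMeans(
        n_clusters=k, n_init=1, random_state=seed, max_iter=max_iter,
        algorithm="lloyd",
    ).fit(x)
    labels = []
    off = 0
    for s in series:
        labels.append(km.labels_[off: off + len(s)].astype(np.int64))
        off += len(s)
    return MicrostateAssignment(
        labels=labels, centers=km.cluster_centers_, k=k, seed=seed,
        dt_save=dt_save,
    )


@dataclass
class ReversibleMSM:
    """Reversible MSM on the largest connected microstate set."""

    lag: float
    T: np.ndarray
    pi: np.ndarray
    eigenvalues: np.ndarray
    implied_timescales: np.ndarray
    active_set: np.ndarray
    discarded_frame_fraction: float = 0.0

    @property
    def n_states(self) -> int:
        return len(self.active_set)


def count_transitions(labels, k: int, steps: int) -> np.ndarray:
    """Sliding-window transition counts at ``steps`` frames of lag."""
    counts = np.zeros((k, k), dtype=np.float64)
    for t in _as_label_list(labels):
        if len(t) <= steps:
            continue
        np.add.at(counts, (t[:-steps], t[steps:]), 1.0)
    return counts


def _largest_connected_set(counts: np.ndarray) -> np.ndarray:
    n_comp, assign = scipy.sparse.csgraph.connected_components(
        counts > 0, directed=True, connection="strong"
    )
    if n_comp == 1:
        return np.arange(counts.shape[0])
    sizes = np.array([
        counts[np.ix_(assign == c, assign == c)].sum()
        for c in range(n_comp)
    ])
    return np.flatnonzero(assign == np.argmax(sizes))


def reversible_mle(
    counts: np.ndarray, tol: float = 1e-10, max_iter: int = 1_000_000
) -> tuple:
    """Reversible maximum-likelihood transition matrix.

    Self-consistent fixed-point iteration on the symmetrized count
    variables ``x_ij`` (Bowman et al. scheme): with ``c_i = sum_j C_ij``
    and ``x_i = sum_j x_ij``,

        x_ij <- (C_ij + C_ji) / (c_i/x_i + c_j/x_j)

    iterated until the element-wise change falls below ``tol``; then
    ``T_ij = x_ij / x_i`` and ``pi_i = x_i / sum(x)``.
    """
    C = np.asarray(counts, dtype=np.float64)
    if C.sum() <= 0:
        raise ValueError("empty count matrix")
    csym = C + C.T
    mask = csym > 0
    x = csym.copy()
    crow = C.sum(axis=1)
    for _ in range(max_iter):
        xrow = x.sum(axis=1)
        q = crow / xrow
        denom = q[:, None] + q[None, :]
        xnew = np.where(mask, csym / np.where(denom > 0, denom, 1.0), 0.0)
        delta = np.abs(xnew - x).max()
        x = xnew
        if delta < tol:
            break
    else:
        warnings.warn("reversible MLE did not converge", stacklevel=2)
    xrow = x.sum(axis=1)
    T = x / xrow[:, None]
    pi = xrow / xrow.sum()
    return T, pi


def _reversible_eigh(T: np.ndarray, pi: np.ndarray):
    """Full real eigendecomposition of a reversible T via symmetrization."""
    sqrt_pi = np.sqrt(pi)
    S = (sqrt_pi[:, None] * T) / sqrt_pi[None, :]
    S = 0.5 * (S + S.T)
    evals, evecs = scipy.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    right = evecs[:, order] / sqrt_pi[:, None]
    return evals, right


def estimate_reversible_msm(
    assignment: MicrostateAssignment, lag: float
) -> ReversibleMSM:
    """Estimate a reversible MSM at physical lag ``lag``.

    Counts use a sliding window within each trajectory (never across
    boundaries), are trimmed to the largest strongly connected set, and the
    transition matrix is the reversible MLE.  Implied timescales are
    ``t_i = -lag / ln|lambda_i|`` for i >= 2.
    """
    steps = lag / assignment.dt_save
    if abs(steps - round(steps)) > 1e-9 or round(steps) < 1:
        raise ValueError("lag must be a positive multiple of dt_save")
    steps = int(round(steps))
    counts = count_transitions(assignment.labels, assignment.k, steps)
    if counts.sum() == 0:
        raise ValueError("lag longer than every trajectory")
    active = _largest_connected_set(counts)
    sub = counts[np.ix_(active, active)]
    total_frames = sum(len(t) for t in assignment.labels)
    in_active = np.isin(np.concatenate(assignment.labels), active)
    discarded = 1.0 - in_active.mean() if total_frames else 0.0
    if discarded > 0:
        logger.info("ergodic trimming discarded %.3f%% of frames",
                    100.0 * discarded)
    T, pi = reversible_mle(sub)
    evals, _ = _reversible_eigh(T, pi)
    lams = evals[1:]
    with np.errstate(divide="ignore"):
        its = -lag / np.log(np.abs(lams))
    return ReversibleMSM(
        lag=lag, T=T, pi=pi, eigenvalues=evals, implied_timescales=its,
        active_set=active, discarded_frame_fraction=float(discarded),
    )


# --------------------------------------------------------------------------
# Chapman-Kolmogorov test
# --------------------------------------------------------------------------

@dataclass
class CKResult:
    ks: np.ndarray
    predicted: list
    estimated: list
    std_errors: list
    max_deviation: float
    max_sigma_deviation: float
    tolerance_sigmas: float
    passed: bool


def ck_test(
    assignment: MicrostateAssignment,
    model,
    k_max: int,
    macro_sets: list | None = None,
    tolerance_sigmas: float = 3.0,
) -> CKResult:
    """Chapman-Kolmogorov test: compare ``P(k tau)`` with ``P(tau)^k``.

    ``model`` is the :class:`ReversibleMSM` (or :class:`MacrostateModel`)
    estimated at lag tau from ``assignment``.  If ``macro_sets`` is given
    (list of microstate-id arrays), trajectories are projected onto those
    sets first.  Deviations are reported element-wise together with
    binomial standard errors of the re-estimated entries; the test passes
    when every deviation is within ``tolerance_sigmas`` standard errors
    (with a small absolute floor for zero-count entries).
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    lag = model.lag
    steps = int(round(lag / assignment.dt_save))
    if macro_sets is not None:
        proj = np.full(assignment.k, -1, dtype=np.int64)
        for m, ids in enumerate(macro_sets):
            proj[np.asarray(ids, dtype=np.int64)] = m
        labels = []
        for t in assignment.labels:
            pt = proj[t]
            if (pt < 0).any():
                pt = pt[pt >= 0]
            labels.append(pt)
        n = len(macro_sets)
    else:
        remap = np.full(assignment.k, -1, dtype=np.int64)
        remap[model.active_set] = np.arange(len(model.active_set))
        labels = []
        for t in assignment.labels:
            rt = remap[t]
            labels.append(rt[rt >= 0])
        n = model.n_states
    T1 = model.T if hasattr(model, "T") else model.P

    ks = np.arange(1, k_max + 1)
    predicted, estimated, std_errors = [], [], []
    max_dev = 0.0
    max_sig = 0.0
    for k in ks:
        if not any(len(t) > k * steps for t in labels):
            raise ValueError(f"insufficient data at lag {k}*tau")
        counts = count_transitions(labels, n, k * steps)
        rows = counts.sum(axis=1)
        # sliding windows overlap k*steps-fold; use effective counts for SEs
        rows_eff = np.maximum(rows / (k * steps), 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            Pk_est = np.where(rows[:, None] > 0, counts / rows[:, None], 0.0)
            se = np.sqrt(
                np.where(rows[:, None] > 0,
                         Pk_est * (1 - Pk_est) / rows_eff[:, None], 0.0)
            )
        Pk_pred = np.linalg.matrix_power(T1, k)
        predicted.append(Pk_pred)
        estimated.append(Pk_est)
        std_errors.append(se)
        dev = np.abs(Pk_pred - Pk_est)
        max_dev = max(max_dev, float(dev.max()))
        if k > 1:
            sig = dev / np.maximum(se, 1e-4)
            max_sig = max(max_sig, float(sig.max()))
    return CKResult(
        ks=ks, predicted=predicted, estimated=estimated,
        std_errors=std_errors, max_deviation=max_dev,
        max_sigma_deviation=max_sig, tolerance_sigmas=tolerance_sigmas,
        passed=max_sig <= tolerance_sigmas,
    )


# --------------------------------------------------------------------------
# Macrostates
# --------------------------------------------------------------------------

@dataclass
class MacrostateModel:
    """PCCA+ coarse-grained macrostate model."""

    memberships: np.ndarray
    P: np.ndarray
    pi_macro: np.ndarray
    lag: float
    n_macro: int
    crisp: np.ndarray = field(default=None)
    labels: list | None = None
    active_set: np.ndarray | None = None

    @property
    def n_states(self) -> int:
        return self.n_macro


def pcca_coarse_grain(
    model: ReversibleMSM,
    n_macro: int,
    assignment: MicrostateAssignment | None = None,
) -> MacrostateModel:
    """PCCA+ membership of microstates into ``n_macro`` macrostates.

    Crisp assignment is by argmax membership (ties broken toward the lowest
    macrostate index).  If ``assignment`` is given, the macrostate
    transition matrix is re-counted from the crisply projected trajectories
    at the model lag; otherwise it is obtained by membership projection of
    the microstate matrix.  ``pi_macro`` aggregates the microstate
    stationary law over crisp sets.
    """
    n = model.n_states
    if not 1 <= n_macro <= n:
        raise ValueError("n_macro out of range")
    if n_macro == 1:
        chi = np.ones((n, 1))
        return MacrostateModel(
            memberships=chi, P=np.array([[1.0]]), pi_macro=np.array([1.0]),
            lag=model.lag, n_macro=1, crisp=np.zeros(n, dtype=np.int64),
            active_set=model.active_set,
        )
    evals, right = _reversible_eigh(model.T, model.pi)
    if n_macro > right.shape[1]:
        raise ValueError("n_macro exceeds the number of resolved eigenvectors")
    chi = pcca_memberships(right[:, :n_macro], model.pi)
    # argmax with lowest-index tie-break (argmax already returns first max)
    crisp = np.argmax(chi, axis=1).astype(np.int64)
    pi_macro = np.array(
        [model.pi[crisp == m].sum() for m in range(n_macro)]
    )
    if assignment is not None:
        proj = np.full(assignment.k, -1, dtype=np.int64)
        proj[model.active_set] = crisp
        steps = int(round(model.lag / assignment.dt_save))
        macro_labels = []
        for t in assignment.labels:
            pt = proj[t]
            macro_labels.append(pt[pt >= 0])
        counts = count_transitions(macro_labels, n_macro, steps)
        P, _ = reversible_mle(counts)
    else:
        # membership projection: P = (chi' diag(pi) chi)^-1 chi' diag(pi) T chi
        w = chi * model.pi[:, None]
        P = np.linalg.solve(w.T @ chi, w.T @ model.T @ chi)
        P = np.clip(P, 0.0, None)
        P = P / P.sum(axis=1, keepdims=True)
    return MacrostateModel(
        memberships=chi, P=P, pi_macro=pi_macro, lag=model.lag,
        n_macro=n_macro, crisp=crisp, active_set=model.active_set,
    )


def select_n_macrostates(
    model: ReversibleMSM, gap_ratio: float = 3.0
) -> int:
    """Macrostate count from the dominant implied-timescale gap.

    Rule (deterministic): consider the maximal leading run of implied
    timescales exceeding the lag; append the lag itself as a sentinel
    "noise floor" after the run; locate the largest ratio ``t_i / t_{i+1}``
    within the run (slowest index wins ties).  If that ratio exceeds
    ``gap_ratio`` the count is ``1 + i``; otherwise 1 (no resolved gap).
    """
    its = np.asarray(model.implied_timescales, dtype=float)
    its = its[np.isfinite(its)]
    run = 0
    while run < len(its) and its[run] > model.lag:
        run += 1
    if run == 0:
        return 1
    t = np.concatenate([its[:run], [model.lag]])
    ratios = t[:-1] / t[1:]
    best = int(np.argmax(ratios))
    if ratios[best] <= gap_ratio:
        return 1
    return best + 2


def bootstrap_uncertainty(
    labels,
    k: int,
    lag: float,
    n_boot: int,
    seed: int,
    dt_save: float = 1.0,
    n_macro: int | None = None,
    percentiles: tuple = (2.5, 97.5),
):
    """Trajectory bootstrap confidence intervals for MSM quantities.

    Resamples whole trajectories with replacement, re-estimates the
    reversible MSM (optionally coarse-grained to ``n_macro`` states), and
    reports percentile intervals for stationary probabilities and implied
    timescales.  Replicates whose resample leaves no connected transitions
    are skipped with a warning and counted.
    """
    labels = _as_label_list(labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 trajectories to bootstrap")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    pis, timescales = [], []
    skipped = 0
    for _ in range(n_boot):
        pick = rng.integers(0, len(labels), size=len(labels))
        sample = [labels[i] for i in pick]
        try:
            asn = MicrostateAssignment(
                labels=sample, centers=np.zeros((k, 1)), k=k, seed=seed,
                dt_save=dt_save,
            )
            m = estimate_reversible_msm(asn, lag)
            if m.n_states < k:
                raise ValueError("replicate lost states")
            if n_macro is not None:
                mm = pcca_coarse_grain(m, n_macro, assignment=asn)
                pis.append(mm.pi_macro)
            else:
                pis.append(m.pi)
            timescales.append(m.implied_timescales)
        except ValueError:
            skipped += 1
    if skipped:
        warnings.warn(
            f"{skipped}/{n_boot} bootstrap replicates skipped", stacklevel=2
        )
    if not pis:
        raise ValueError("all bootstrap replicates failed")
    pis = np.array(pis)
    nts = min(len(t) for t in timescales)
    ts = np.array([t[:nts] for t in timescales])
    lo, hi = percentiles
    return {
        "pi": np.percentile(pis, [lo, hi], axis=0),
        "pi_samples": pis,
        "timescales": np.percentile(ts, [lo, hi], axis=0),
        "timescale_samples": ts,
        "n_skipped": skipped,
    }
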