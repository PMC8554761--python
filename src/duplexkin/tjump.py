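"""Relaxation-rate extraction and two-state temperature-jump algebra.

Extracts slow (dissociation) and fast (fraying) first-passage times from
relaxation ensembles, fits exponential survival curves, applies the
two-state mass-action algebra for self-complementary oligomers
(``2S <-> D``), fits temperature-jump time traces to a stretched
exponential plus two exponentials, and calibrates simulated
rate-vs-temperature curves against experimental ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from . import constants as C

__all__ = [
    "FirstPassageSet",
    "TwoStateInputs",
    "TraceFit",
    "extract_first_passage",
    "fit_survival_rate",
    "rates_from_kd",
    "two_state_rates",
    "fit_tjump_trace",
    "calibrate_to_experiment",
]


@dataclass
class FirstPassageSet:
    """First-passage event times (ns) with administrative censoring."""

    event_times: np.ndarray
    n_censored: int
    t_max: float
    event_kind: str

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        if len(self.event_times) and (
            self.event_times.min() <= 0 or self.event_times.max() > self.t_max
        ):
            raise ValueError("event times must lie in (0, t_max]")
        if self.n_censored < 0:
            raise ValueError("negative censored count")

    @property
    def n_traj(self) -> int:
        return len(self.event_times) + self.n_censored


@dataclass(frozen=True)
class TwoStateInputs:
    """Observed slow rate plus equilibrium duplex fraction and concentration."""

    theta: float
    c_tot: float
    lambda_slow: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        if self.c_tot <= 0:
            raise ValueError("c_tot must be positive")


@dataclass
class TraceFit:
    """Stretched-exponential + two-exponential trace fit parameters."""

    A: float
    B: float
    C: float
    tau_fast: float
    tau_slow: float
    tau_cool: float
    beta_fast: float
    residual: float
    n_starts_converged: int

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return (
            self.A * np.exp(-((t / self.tau_fast) ** self.beta_fast))
            + self.B * np.exp(-t / self.tau_slow)
            + self.C * np.exp(-t / self.tau_cool)
        )


# --------------------------------------------------------------------------
# First-passage extraction
# --------------------------------------------------------------------------

def _pair_distance(frames, i, j):
    """Distance between strand-1 base i and strand-2 base j per frame."""
    diff = frames[:, 0, i, :].astype(np.float64) - frames[:, 1, j, :].astype(np.float64)
    return np.sqrt((diff * diff).sum(axis=-1))


def extract_first_passage(
    ensemble,
    kind: str,
    bound_cutoff: float = C.BOUND_CUTOFF,
    dissoc_cutoff: float = C.DISSOC_CUTOFF,
) -> FirstPassageSet:
    """First-passage times for dissociation or fraying events.

    Dissociation: first frame at which both central native pairs exceed
    ``dissoc_cutoff``.  Fraying: first frame at which either terminal
    native pair exceeds ``bound_cutoff``.  Trajectories with no event
    before ``t_max`` are censored.
    """
    if kind not in ("dissociation", "fraying"):
        raise ValueError("kind must be 'dissociation' or 'fraying'")
    L = C.SEQ_LENGTH
    mid = L // 2
    events = []
    n_censored = 0
    for traj in ensemble.trajectories:
        if traj.frames is None:
            raise ValueError("ensemble lacks coordinates")
        if traj.truth_labels is not None and traj.truth_labels[0] != "H":
            raise ValueError("trajectory does not start hybridized")
        f = traj.frames
        if kind == "dissociation":
            d1 = _pair_distance(f, mid - 1, mid)
            d2 = _pair_distance(f, mid, mid - 1)
            hit = (d1 > dissoc_cutoff) & (d2 > dissoc_cutoff)
        else:
            d1 = _pair_distance(f, 0, L - 1)
            d2 = _pair_distance(f, L - 1, 0)
            hit = (d1 > bound_cutoff) | (d2 > bound_cutoff)
        idx = np.flatnonzero(hit)
        if len(idx) == 0 or idx[0] == 0:
            if len(idx) and idx[0] == 0:
                raise ValueError("trajectory does not start hybridized")
            n_censored += 1
        else:
            events.append(idx[0] * traj.dt_save)
    return FirstPassageSet(
        event_times=np.array(events),
        n_censored=n_censored,
        t_max=ensemble.t_max,
        event_kind=kind,
    )


def fit_survival_rate(
    fps: FirstPassageSet,
    n_boot: int = 200,
    seed: int = 0,
    ci: float = 95.0,
):
    """Least-squares exponential fit to the empirical survival fraction.

    Fits ``exp(-k t)`` to the survival fraction evaluated at the observed
    event times; censored trajectories stay in the at-risk denominator
    throughout (administrative censoring at ``t_max``).  Returns
    ``(k, (lo, hi))`` in 1/ns with a trajectory-bootstrap confidence
    interval.
    """
    if len(fps.event_times) == 0:
        raise ValueError("no uncensored events to fit")

    def _fit(times, n_total):
        order = np.sort(np.asarray(times, dtype=float))
        surv = 1.0 - np.arange(1, len(order) + 1) / n_total
        scale = order.mean()
        t = order / scale

        def obj(kk):
            return float(((np.exp(-kk * t) - surv) ** 2).sum())

        res = minimize_scalar(obj, bounds=(1e-12, 1e4), method="bounded",
                              options={"xatol": 1e-14})
        return res.x / scale

    k_hat = _fit(fps.event_times, fps.n_traj)
    rng = np.random.default_rng(seed)
    status = np.concatenate([
        fps.event_times, np.full(fps.n_censored, np.nan)
    ])
    boots = []
    for _ in range(n_boot):
        sample = rng.choice(status, size=len(status), replace=True)
        ev = sample[~np.isnan(sample)]
        if len(ev) == 0:
            continue
        boots.append(_fit(ev, len(sample)))
    if boots:
        half = (100.0 - ci) / 2.0
        lo, hi = np.percentile(boots, [half, 100.0 - half])
    else:
        lo = hi = k_hat
    return float(k_hat), (float(lo), float(hi))


# --------------------------------------------------------------------------
# Two-state T-jump algebra (self-complementary oligomers, 2S <-> D)
# --------------------------------------------------------------------------

def rates_from_kd(K_d: float, S_Tf: float, lambda_slow: float) -> dict:
    """Recast the observed slow rate into k_d/k_a given K_d and [S]_Tf.

    ``lambda_slow = k_d + 4 k_a [S]`` with ``K_d = k_d / k_a`` gives

        k_d = lambda_slow K_d / (K_d + 4 [S]),
        k_a = lambda_slow / (K_d + 4 [S]).

    In the ``[S] -> 0`` limit the observed rate is pure dissociation
    (``k_d -> lambda_slow``).
    """
    if K_d < 0 or S_Tf < 0:
        raise ValueError("K_d and S_Tf must be non-negative")
    denom = K_d + 4.0 * S_Tf
    if denom <= 0:
        raise ValueError("K_d + 4 S_Tf must be positive")
    return {
        "K_d": K_d,
        "S_Tf": S_Tf,
        "k_d_slow": lambda_slow * K_d / denom,
        "k_a_slow": lambda_slow / denom,
    }


def two_state_rates(inputs: TwoStateInputs) -> dict:
    """Dissociation/association rates from the observed slow relaxation.

    For a self-complementary duplex ``2S <-> D`` with dissociation constant
    ``K_d = [S]^2/[D]`` the linearized relaxation rate is

        lambda_slow = k_d + 4 k_a [S],

    so with ``K_d = 2 c_tot (1-theta)^2 / theta`` and
    ``[S] = (1-theta) c_tot``:

        k_d = lambda_slow K_d / (K_d + 4 [S]),
        k_a = lambda_slow / (K_d + 4 [S]).

    Concentration units of ``c_tot`` propagate to ``K_d``, ``S_Tf`` and the
    bimolecular ``k_a``; ``lambda_slow`` units propagate to the rates.
    """
    th = inputs.theta
    if th in (0.0, 1.0):
        if th == 1.0:
            return {
                "K_d": 0.0,
                "S_Tf": 0.0,
                "k_d_slow": inputs.lambda_slow,
                "k_a_slow": np.inf,
            }
        raise ValueError("theta = 0: no duplex present, K_d degenerate")
    K_d = 2.0 * inputs.c_tot * (1.0 - th) ** 2 / th
    S = (1.0 - th) * inputs.c_tot
    return rates_from_kd(K_d, S, inputs.lambda_slow)


# --------------------------------------------------------------------------
# Trace fitting
# --------------------------------------------------------------------------

def _trace_model(t, A, B, Cc, tau_f, r1, r2, beta):
    tau_s = tau_f * np.exp(r1)
    tau_c = tau_s * np.exp(r2)
    return (
        A * np.exp(-((t / tau_f) ** beta))
        + B * np.exp(-t / tau_s)
        + Cc * np.exp(-t / tau_c)
    )


def fit_tjump_trace(
    times: np.ndarray,
    signal: np.ndarray,
    init: dict | None = None,
    n_starts: int = 10,
    seed: int = 0,
) -> TraceFit:
    """Fit a trace to ``A exp(-(t/tau_f)^beta) + B exp(-t/tau_s) + C exp(-t/tau_c)``.

    Nonlinear least squares with the ordering constraint
    ``tau_fast < tau_slow < tau_cool`` enforced structurally through
    log-ratio parameters and ``beta in (0, 1]``.  Multistart over seeded
    initializations; the best-residual solution is returned.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(signal, dtype=float)
    if len(t) < 8:
        raise ValueError("need at least 8 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    if t[0] <= 0:
        raise ValueError("times must be positive")
    if t[-1] / t[0] < 100.0:
        raise ValueError("time grid must span at least two decades")
    rng = np.random.default_rng(seed)
    span = np.log(t[-1]) - np.log(t[0])
    amp = max(np.abs(y).max(), 1e-12)
    lo = [-5 * amp, -5 * amp, -5 * amp, np.log(t[0] / 10), 1e-6, 1e-6, 1e-3]
    hi = [5 * amp, 5 * amp, 5 * amp, np.log(t[-1] * 10), 30.0, 30.0, 1.0]

    starts = []
    if init is not None:
        tau_f = init.get("tau_fast", t[0] * 10)
        tau_s = init.get("tau_slow", tau_f * 50)
        tau_c = init.get("tau_cool", tau_s * 50)
        starts.append([
            init.get("A", amp), init.get("B", amp), init.get("C", amp),
            np.log(tau_f), np.log(tau_s / tau_f), np.log(tau_c / tau_s),
            init.get("beta_fast", 0.7),
        ])
    for _ in range(n_starts):
        lf = np.log(t[0]) + rng.uniform(0.0, 0.4) * span
        starts.append([
            amp * rng.uniform(0.2, 1.5), amp * rng.uniform(-1.5, 1.5),
            amp * rng.uniform(-1.5, 1.5), lf,
            rng.uniform(0.5, span), rng.uniform(0.5, span),
            rng.uniform(0.2, 1.0),
        ])

    def resid(p):
        A, B, Cc, ltf, r1, r2, beta = p
        return _trace_model(t, A, B, Cc, np.exp(ltf), r1, r2, beta) - y

    best = None
    n_ok = 0
    diagnostics = []
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        try:
            res = least_squares(resid, x0, bounds=(lo, hi), max_nfev=20000)
        except Exception as exc:  # pragma: no cover - optimizer failure path
            diagnostics.append(str(exc))
            continue
        if not np.all(np.isfinite(res.x)):
            diagnostics.append("non-finite solution")
            continue
        n_ok += 1
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError(
            "all trace-fit starts failed: " + "; ".join(diagnostics)
        )
    A, B, Cc, ltf, r1, r2, beta = best.x
    tau_f = float(np.exp(ltf))
    tau_s = tau_f * float(np.exp(r1))
    tau_c = tau_s * float(np.exp(r2))
    return TraceFit(
        A=float(A), B=float(B), C=float(Cc),
        tau_fast=tau_f, tau_slow=tau_s, tau_cool=tau_c,
        beta_fast=float(beta), residual=float(2 * best.cost),
        n_starts_converged=n_ok,
    )


# --------------------------------------------------------------------------
# Calibration against experimental rate curves
# --------------------------------------------------------------------------

def calibrate_to_experiment(
    sim_curve: np.ndarray,
    exp_curve: np.ndarray,
    max_shift: float = 30.0,
) -> dict:
    """Two-parameter calibration of a simulated rate-vs-temperature curve.

    Finds ``(s, dT)`` least-squares-matching ``sim_rate(T + dT) = s *
    exp_rate(T)`` in log-rate, interpolating the simulated curve linearly
    in log-rate between tabulated points.  ``s`` is the acceleration factor
    of the simulation relative to experiment and ``dT`` the shift added to
    simulated temperatures to align the curves (a simulation that
    under-predicts temperatures by 4 K yields dT = -4).
    """
    sim = np.asarray(sim_curve, dtype=float)
    exp = np.asarray(exp_curve, dtype=float)
    if sim.ndim != 2 or exp.ndim != 2 or sim.shape[1] != 2 or exp.shape[1] != 2:
        raise ValueError("curves must be (n, 2) arrays of (T, rate)")
    if len(sim) < 3 or len(exp) < 3:
        raise ValueError("curves need at least 3 points (under-determined)")
    sim = sim[np.argsort(sim[:, 0])]
    logsim = np.log(sim[:, 1])
    logexp = np.log(exp[:, 1])

    def resid(p):
        log_s, dT = p
        shifted = exp[:, 0] + dT
        if shifted.max() < sim[0, 0] or shifted.min() > sim[-1, 0]:
            return np.full(len(exp), 1e3)
        pred = np.interp(shifted, sim[:, 0], logsim)
        return pred - (log_s + logexp)

    best = None
    for dT0 in np.linspace(-max_shift, max_shift, 13):
        res = least_squares(
            resid, x0=[0.0, dT0],
            bounds=([-50.0, -max_shift], [50.0, max_shift]),
        )
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise ValueError("no overlapping temperature range for any shift")
    log_s, dT = best.x
    return {
        "time_scale": float(np.exp(log_s)),
        "temp_shift": float(dT),
        "residuals": resid(best.x),
        "rms_log_residual": float(np.sqrt(np.mean(resid(best.x) ** 2))),
    }
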