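"""Synthetic two-strand duplex trajectory generator.

Emulates the statistical structure of coarse-grained duplex simulations:
a continuous-time Markov jump process over a small set of metastable
macrostates (hybridized, register-shifted, frayed, dissociated), dressed
with per-state coordinate templates, mean-reverting coordinate jitter, and
fast terminal-pair fraying fluctuations.  All ground-truth numbers live in
:mod:`duplexkin.constants`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import lfilter

from . import constants as C

__all__ = [
    "DuplexSequence",
    "KineticPreset",
    "Trajectory",
    "RelaxationEnsemble",
    "build_preset",
    "build_templates",
    "simulate_equilibrium",
    "simulate_relaxation",
    "sample_label_path",
    "stationary_at",
    "find_melting_factor",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(bases: str) -> str:
    return bases.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DuplexSequence:
    """A 10-base self-complementary strand, written 5'->3'."""

    name: str
    bases: str

    def __post_init__(self) -> None:
        if len(self.bases) != C.SEQ_LENGTH:
            raise ValueError(
                f"sequence must have exactly {C.SEQ_LENGTH} bases, "
                f"got {len(self.bases)}"
            )
        if set(self.bases) - set("ACGT"):
            raise ValueError(f"invalid bases in {self.bases!r}")
        if reverse_complement(self.bases) != self.bases:
            raise ValueError(
                f"sequence {self.bases!r} is not self-complementary"
            )
        if self.name in C.PRESET_SEQUENCES:
            expected = C.PRESET_SEQUENCES[self.name]
            if self.bases != expected:
                raise ValueError(
                    f"preset {self.name!r} requires bases {expected!r}"
                )

    @classmethod
    def from_name(cls, name: str) -> "DuplexSequence":
        if name not in C.PRESET_SEQUENCES:
            raise ValueError(
                f"unknown sequence preset {name!r}; "
                f"choose from {sorted(C.PRESET_SEQUENCES)}"
            )
        return cls(name=name, bases=C.PRESET_SEQUENCES[name])

    @property
    def has_gc_core(self) -> bool:
        """True if positions 5 and 6 (1-based) form a G:C/C:G step."""
        core = self.bases[4:6]
        return set(core) <= {"G", "C"}


def _validate_label(label: str) -> str:
    if label not in C.MACROSTATE_LABELS:
        raise ValueError(
            f"unknown macrostate label {label!r}; "
            f"admissible labels are {C.MACROSTATE_LABELS}"
        )
    return label


@dataclass(frozen=True)
class KineticPreset:
    """Ground-truth kinetic network plus coordinate emission parameters.

    ``rate_matrix`` holds transition rates in 1/ns (off-diagonal >= 0, rows
    summing to zero), ``stationary`` its equilibrium law, and ``templates``
    per-state base-center coordinates of shape (n_states, 2, 10, 3) in nm.
    """

    sequence: DuplexSequence
    states: tuple
    rate_matrix: np.ndarray
    stationary: np.ndarray
    templates: np.ndarray
    jitter_sigma: float = C.JITTER_SIGMA
    jitter_corr_time: float = C.JITTER_CORR_TIME
    fray_toggle_rate: float = C.FRAY_TOGGLE_RATE
    temperature_factor: float = 0.0

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, label: str) -> int:
        return self.states.index(_validate_label(label))

    def validate(self) -> None:
        n = self.n_states
        if n == 0:
            raise ValueError("empty state set")
        for s in self.states:
            _validate_label(s)
        Q = np.asarray(self.rate_matrix, dtype=float)
        pi = np.asarray(self.stationary, dtype=float)
        if Q.shape != (n, n):
            raise ValueError("rate_matrix shape does not match state set")
        off = Q - np.diag(np.diag(Q))
        if off.min() < 0:
            raise ValueError("invariant violated: off-diagonal rates >= 0")
        if np.abs(Q.sum(axis=1)).max() > 1e-10:
            raise ValueError("invariant violated: rate-matrix rows sum to 0")
        if abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError(
                "invariant violated: stationary distribution sums to 1"
            )
        db = np.abs(pi[:, None] * Q - (pi[:, None] * Q).T)
        if db.max() > 1e-10:
            raise ValueError(
                "invariant violated: detailed balance pi_i q_ij = pi_j q_ji"
            )
        name = self.sequence.name
        if name in C.PRESET_STATES and self.states != C.PRESET_STATES[name]:
            raise ValueError(
                f"invariant violated: preset {name} state set must be "
                f"{C.PRESET_STATES[name]}"
            )

    def with_temperature(self, u: float) -> "KineticPreset":
        """Return the preset with its rates rescaled by the factor ``u``.

        Rates toward less-bound states are multiplied by ``exp(+u*db)`` and
        their reverses by ``exp(-u*db)`` where ``db`` is the boundness drop,
        which re-establishes detailed balance at the tilted stationary law
        ``pi_i' ~ pi_i exp(-2 u b_i)``.
        """
        if u == self.temperature_factor:
            return self
        du = u - self.temperature_factor
        b = np.array([C.BOUNDNESS[s] for s in self.states])
        Q = np.array(self.rate_matrix, dtype=float)
        scale = np.exp(du * (b[:, None] - b[None, :]))
        np.fill_diagonal(scale, 0.0)
        Q = Q * scale
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        pi = self.stationary * np.exp(-2.0 * du * b)
        pi = pi / pi.sum()
        return replace(
            self, rate_matrix=Q, stationary=pi, temperature_factor=u
        )


@dataclass
class Trajectory:
    """Per-frame base-center coordinates with ground-truth state labels."""

    frames: np.ndarray | None
    dt_save: float
    seed: int
    truth_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.dt_save <= 0:
            raise ValueError("dt_save must be positive")
        if self.frames is not None:
            if self.frames.ndim != 4 or self.frames.shape[1:] != (2, C.SEQ_LENGTH, 3):
                raise ValueError("frames must have shape (n, 2, 10, 3)")
            if self.frames.shape[0] < 1:
                raise ValueError("need at least one frame")
            if not np.all(np.isfinite(self.frames)):
                raise ValueError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        if self.frames is not None:
            return self.frames.shape[0]
        return len(self.truth_labels)


@dataclass
class RelaxationEnsemble:
    """Many short trajectories started hybridized at a common bias ``u``."""

    trajectories: list
    temperature_factor: float
    t_max: float
    start_label: str = "H"


# --------------------------------------------------------------------------
# Templates
# --------------------------------------------------------------------------

def build_templates(sequence: DuplexSequence, states: Sequence[str]) -> np.ndarray:
    """Straight-ladder coordinate templates, shape (n_states, 2, 10, 3) nm.

    Strand 1 base i sits at x = i*RISE on the y = 0 rail; strand 2 base j at
    x = (L-1-j+k)*RISE on the y = PAIR_SEP rail for register offset k, so
    native-style contacts form on the anti-diagonal i + j = L - 1 + k.  The
    dissociated template separates the rails by DISSOC_SEP; the F4 template
    opens the four native terminal A:T pairs on the low-index end of strand 1.
    """
    L = C.SEQ_LENGTH
    idx = np.arange(L, dtype=float)
    out = np.zeros((len(states), 2, L, 3))
    for si, label in enumerate(states):
        _validate_label(label)
        k = C.REGISTER_OFFSET[label]
        out[si, 0, :, 0] = idx * C.RISE
        out[si, 1, :, 0] = (L - 1 - idx + k) * C.RISE
        out[si, 1, :, 1] = C.PAIR_SEP
        if label == "D":
            out[si, 1, :, 1] = C.DISSOC_SEP
        elif label == "F4":
            # break native pairs (0..3): s1 bases 0..3 pair s2 bases 9..6
            disp = C.FRAY_DISP + 0.45  # clear break, ~2.1 nm pair distance
            out[si, 0, 0:4, 2] += disp
            out[si, 1, 6:10, 2] -= disp
    return out


# --------------------------------------------------------------------------
# Preset construction
# --------------------------------------------------------------------------

def _rates_from_fluxes(
    states: Sequence[str], pi: np.ndarray, fluxes: Mapping
) -> np.ndarray:
    index = {s: i for i, s in enumerate(states)}
    n = len(states)
    Q = np.zeros((n, n))
    for (a, b), s in fluxes.items():
        if a not in index or b not in index:
            raise ValueError(f"flux references unknown state pair {(a, b)}")
        if s < 0:
            raise ValueError("invariant violated: off-diagonal rates >= 0")
        Q[index[a], index[b]] = s / pi[index[a]]
        Q[index[b], index[a]] = s / pi[index[b]]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def build_preset(name: str, overrides: Mapping | None = None) -> KineticPreset:
    """Build a named (or fully custom) ground-truth kinetic preset.

    Named presets are deterministic.  ``overrides`` may replace any of
    ``stationary`` (mapping label -> probability), ``fluxes`` (mapping state
    pairs -> symmetrized flux in 1/ns), ``states``, ``sequence``/``bases``,
    and the scalar emission parameters.  A ``custom`` preset must provide at
    least ``bases``, ``states``, ``stationary`` and ``fluxes``.
    """
    overrides = dict(overrides or {})
    if name in C.PRESET_SEQUENCES:
        sequence = DuplexSequence.from_name(name)
        states = tuple(overrides.pop("states", C.PRESET_STATES[name]))
        stat_map = dict(C.PRESET_STATIONARY[name])
        stat_map.update(overrides.pop("stationary", {}))
        fluxes = dict(C.PRESET_FLUXES[name])
        fluxes.update(overrides.pop("fluxes", {}))
    elif name == "custom":
        try:
            bases = overrides.pop("bases")
            states = tuple(overrides.pop("states"))
            stat_map = dict(overrides.pop("stationary"))
            fluxes = dict(overrides.pop("fluxes"))
        except KeyError as exc:
            raise ValueError(
                f"custom preset requires parameter {exc.args[0]!r}"
            ) from exc
        sequence = DuplexSequence(name="custom", bases=bases)
    else:
        raise ValueError(
            f"unknown preset {name!r}; choose from "
            f"{sorted(C.PRESET_SEQUENCES)} or 'custom'"
        )
    pi = np.array([stat_map[s] for s in states], dtype=float)
    if abs(pi.sum() - 1.0) > 1e-12:
        raise ValueError(
            "invariant violated: stationary distribution sums to 1"
        )
    Q = _rates_from_fluxes(states, pi, fluxes)
    preset = KineticPreset(
        sequence=sequence,
        states=states,
        rate_matrix=Q,
        stationary=pi,
        templates=build_templates(sequence, states),
        **overrides,
    )
    preset.validate()
    return preset


# --------------------------------------------------------------------------
# Stochastic simulation
# --------------------------------------------------------------------------

def sample_label_path(
    Q: np.ndarray,
    start: int,
    t_end: float,
    rng: np.random.Generator,
):
    """Gillespie (direct SSA) sample of a CTMC path.

    Returns ``(times, states)`` where ``times[0] = 0`` and ``states[m]``
    holds on ``[times[m], times[m+1])``; the path covers ``[0, t_end]``.
    """
    Q = np.asarray(Q, dtype=float)
    exit_rates = -np.diag(Q)
    n = Q.shape[0]
    jump_p = np.where(np.eye(n, dtype=bool), 0.0, Q)
    with np.errstate(invalid="ignore", divide="ignore"):
        jump_p = jump_p / exit_rates[:, None]
    times = [0.0]
    states = [int(start)]
    t, s = 0.0, int(start)
    while True:
        rate = exit_rates[s]
        if rate <= 0.0:
            break
        t += rng.exponential(1.0 / rate)
        if t >= t_end:
            break
        s = int(rng.choice(n, p=jump_p[s]))
        times.append(t)
        states.append(s)
    return np.array(times), np.array(states, dtype=np.int64)


def _labels_on_grid(times, states, n_frames, dt_save):
    grid = np.arange(n_frames) * dt_save
    idx = np.searchsorted(times, grid, side="right") - 1
    return states[idx]


def _ar1_jitter(rng, n_frames, dt_save, sigma, corr_time, shape):
    """Stationary AR(1) noise with stddev sigma and correlation time."""
    phi = float(np.exp(-dt_save / corr_time))
    innov = sigma * np.sqrt(1.0 - phi * phi)
    w = rng.standard_normal((n_frames,) + shape).astype(np.float32)
    x0 = sigma * rng.standard_normal(shape).astype(np.float32)
    b, a = np.array([innov], dtype=np.float32), np.array([1.0, -phi], dtype=np.float32)
    flat = w.reshape(n_frames, -1)
    zi = (phi * x0).reshape(1, -1).astype(np.float32)
    y, _ = lfilter(b, a, flat, axis=0, zi=zi)
    return y.reshape((n_frames,) + shape).astype(np.float32)


def _two_state_toggle(rng, n_frames, dt_save, relax_rate, p_on, initial=None):
    """Exact grid sampling of a two-state toggle via Doeblin regeneration."""
    resample = rng.random(n_frames) < (1.0 - np.exp(-relax_rate * dt_save))
    resample[0] = True
    proposal = rng.random(n_frames) < p_on
    if initial is not None:
        proposal[0] = bool(initial)
    pos = np.where(resample, np.arange(n_frames), 0)
    last = np.maximum.accumulate(pos)
    return proposal[last]


def _emit_frames(preset, label_idx, dt_save, rng, fray_initial=None):
    n = len(label_idx)
    frames = preset.templates[label_idx].astype(np.float32)
    frames += _ar1_jitter(
        rng, n, dt_save, preset.jitter_sigma, preset.jitter_corr_time,
        (2, C.SEQ_LENGTH, 3),
    )
    # terminal-pair fraying: end A = native pair (s1[0], s2[L-1]),
    # end B = native pair (s1[L-1], s2[0]); displaced only in bound states.
    L = C.SEQ_LENGTH
    bound = np.array([s != "D" for s in preset.states])[label_idx]
    f4 = np.array([s == "F4" for s in preset.states])[label_idx]
    fray_a = _two_state_toggle(
        rng, n, dt_save, preset.fray_toggle_rate, C.FRAY_EQ_PROB,
        initial=fray_initial,
    )
    fray_b = _two_state_toggle(
        rng, n, dt_save, preset.fray_toggle_rate, C.FRAY_EQ_PROB,
        initial=fray_initial,
    )
    # end A coincides with the F4 template's opened run; skip it there
    sel_a = fray_a & bound & ~f4
    frames[sel_a, 0, 0, 2] += C.FRAY_DISP
    frames[sel_a, 1, L - 1, 2] -= C.FRAY_DISP
    sel_b = fray_b & bound
    frames[sel_b, 0, L - 1, 2] += C.FRAY_DISP
    frames[sel_b, 1, 0, 2] -= C.FRAY_DISP
    return frames


def simulate_equilibrium(
    preset: KineticPreset,
    n_frames: int,
    dt_save: float,
    seed: int,
    include_coordinates: bool = True,
) -> Trajectory:
    """Sample an equilibrium trajectory of the preset's jump process.

    The macrostate path is drawn by the direct stochastic simulation
    algorithm started from the stationary law, discretized on the
    ``dt_save`` grid, and dressed with template coordinates, AR(1) jitter
    and terminal-pair fraying.  Identical seeds give identical output.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if dt_save <= 0:
        raise ValueError("dt_save must be positive")
    if preset.n_states == 0:
        raise ValueError("empty state set")
    ss = np.random.SeedSequence(seed)
    rng_path, rng_coord = (np.random.default_rng(s) for s in ss.spawn(2))
    start = int(rng_path.choice(preset.n_states, p=preset.stationary))
    times, states = sample_label_path(
        preset.rate_matrix, start, n_frames * dt_save, rng_path
    )
    label_idx = _labels_on_grid(times, states, n_frames, dt_save)
    frames = None
    if include_coordinates:
        frames = _emit_frames(preset, label_idx, dt_save, rng_coord)
    labels = np.asarray(preset.states, dtype=object)[label_idx]
    return Trajectory(
        frames=frames, dt_save=dt_save, seed=seed, truth_labels=labels
    )


def simulate_relaxation(
    preset: KineticPreset,
    u: float,
    n_traj: int,
    t_max: float,
    seed: int,
    dt_save: float = 0.1,
    include_coordinates: bool = True,
) -> RelaxationEnsemble:
    """Sample ``n_traj`` trajectories started in H under temperature bias u.

    Per-trajectory random streams are spawned from the master seed with a
    counter-based splitting rule, so trajectories are independent and the
    ensemble is reproducible.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if u < 0:
        raise ValueError("u must be >= 0")
    hot = preset.with_temperature(u)
    start = hot.state_index("H")
    n_frames = max(int(np.floor(t_max / dt_save)) + 1, 1)
    trajs = []
    for i, child in enumerate(np.random.SeedSequence(seed).spawn(n_traj)):
        rng_path, rng_coord = (np.random.default_rng(s) for s in child.spawn(2))
        times, states = sample_label_path(
            hot.rate_matrix, start, n_frames * dt_save, rng_path
        )
        label_idx = _labels_on_grid(times, states, n_frames, dt_save)
        frames = None
        if include_coordinates:
            # relaxation trajectories start fully paired: fraying toggles off
            frames = _emit_frames(
                hot, label_idx, dt_save, rng_coord, fray_initial=False
            )
        labels = np.asarray(hot.states, dtype=object)[label_idx]
        trajs.append(
            Trajectory(
                frames=frames, dt_save=dt_save, seed=seed + i,
                truth_labels=labels,
            )
        )
    return RelaxationEnsemble(
        trajectories=trajs, temperature_factor=u, t_max=t_max
    )


# --------------------------------------------------------------------------
# Analytic stationary law under temperature bias, and melting-point search
# --------------------------------------------------------------------------

def stationary_at(preset: KineticPreset, u: float) -> np.ndarray:
    """Analytic stationary law of the u-biased chain (no sampling)."""
    b = np.array([C.BOUNDNESS[s] for s in preset.states])
    du = u - preset.temperature_factor
    w = preset.stationary * np.exp(-2.0 * du * b)
    return w / w.sum()


def find_melting_factor(preset: KineticPreset, tol: float = 1e-10) -> float:
    """Bisection for u* at which the dissociated state holds mass 1/2.

    Uses the analytic stationary law; the D mass is strictly monotone in u
    by the boundness-potential construction.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if "D" not in preset.states:
        raise ValueError("preset lacks a dissociated state D")
    d = preset.state_index("D")

    def mass(u: float) -> float:
        return float(stationary_at(preset, u)[d])

    lo, hi = -50.0, 50.0
    if not (mass(lo) < 0.5 < mass(hi)):
        raise ValueError("melting point not bracketed in u in [-50, 50]")
    while hi - lo > 1e-14:
        mid = 0.5 * (lo + hi)
        if abs(mass(mid) - 0.5) <= tol:
            return mid
        if mass(mid) < 0.5:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
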