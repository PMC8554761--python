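"""Register classification and transition-path analysis.

Geometric classification of frames into duplex macrostates by base-pairing
register, plus committor, reactive-flux pathway fraction, and mean
first-passage time computations on macrostate transition matrices.

Sign convention: a positive register offset ``k`` (strand 2 translated by
``+k`` bases along the ladder axis, contacts on the anti-diagonal
``i + j = L - 1 + k``) leaves 5' overhangs on both strands and is labeled
``5S|k|``; negative offsets are labeled ``3S|k|``.  The convention is
asserted against generator template frames in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import constants as C
from .duplex_synth import DuplexSequence

__all__ = [
    "RegisterContactProfile",
    "register_contact_profile",
    "classify_macrostate",
    "classify_frames",
    "committor",
    "pathway_fraction",
    "mfpt",
    "mfpt_matrix",
    "net_flux",
    "PathwayReport",
    "pathway_report",
    "UNASSIGNED",
]

UNASSIGNED = "unassigned"


@dataclass
class RegisterContactProfile:
    """Intact-contact counts per register offset plus terminal fraying flags."""

    offsets: np.ndarray
    counts: np.ndarray
    bound_cutoff: float
    frayed_low: bool
    frayed_high: bool

    def count_at(self, k: int) -> int:
        return int(self.counts[list(self.offsets).index(k)])


def _offset_counts(sym: np.ndarray, bound_cutoff: float) -> tuple:
    L = sym.shape[0]
    offsets = np.arange(-(L - 2), L - 1)
    intact = sym < bound_cutoff
    counts = np.array(
        [int(np.trace(np.fliplr(intact), offset=-k)) for k in offsets]
    )
    return offsets, counts


def register_contact_profile(
    d: np.ndarray, bound_cutoff: float = C.BOUND_CUTOFF
) -> RegisterContactProfile:
    """Contact profile of one interbase distance matrix.

    An intact contact is a strand-swap symmetrized distance below
    ``bound_cutoff``; contacts at register offset k lie on the
    anti-diagonal ``i + j = L - 1 + k``.
    """
    d = np.asarray(d, dtype=float)
    L = d.shape[0]
    sym = 0.5 * (d + d.T)
    offsets, counts = _offset_counts(sym, bound_cutoff)
    native = np.array([sym[i, L - 1 - i] for i in range(L)])
    return RegisterContactProfile(
        offsets=offsets,
        counts=counts,
        bound_cutoff=bound_cutoff,
        frayed_low=bool(native[0] >= bound_cutoff),
        frayed_high=bool(native[L - 1] >= bound_cutoff),
    )


def _terminal_at_runs(sequence: DuplexSequence) -> tuple:
    """Native-pair index runs of consecutive A:T pairs at each terminus."""
    bases = sequence.bases
    L = len(bases)
    low = []
    for i in range(L):
        if bases[i] in "AT":
            low.append(i)
        else:
            break
    high = []
    for i in range(L - 1, -1, -1):
        if bases[i] in "AT":
            high.append(i)
        else:
            break
    return tuple(low), tuple(high)


def classify_macrostate(
    d: np.ndarray,
    sequence: DuplexSequence,
    bound_cutoff: float = C.BOUND_CUTOFF,
    dissoc_cutoff: float = C.DISSOC_CUTOFF,
) -> str:
    """Macrostate label of one frame from its interbase distance matrix.

    Dissociated (D) when both central native pairs exceed ``dissoc_cutoff``
    and no register offset carries two or more intact contacts; otherwise
    the offset with the maximal intact-contact count (ties broken toward
    smaller |k|, then positive k) determines H / 5S2 / 3S2 / 5S4 / 3S4.
    F4 requires register 0, both central contacts intact, a central G:C
    core, and one terminal run of >= 4 native A:T contacts entirely broken.
    Frames matching no rule return the sentinel ``"unassigned"``.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("malformed distance matrix")
    return classify_frames(
        d[None], sequence, bound_cutoff, dissoc_cutoff
    )[0]


def classify_frames(
    dmats: np.ndarray,
    sequence: DuplexSequence,
    bound_cutoff: float = C.BOUND_CUTOFF,
    dissoc_cutoff: float = C.DISSOC_CUTOFF,
) -> np.ndarray:
    """Vectorized :func:`classify_macrostate` over a stack (n, L, L)."""
    if not (0 < bound_cutoff < dissoc_cutoff):
        raise ValueError("require 0 < bound_cutoff < dissoc_cutoff")
    d = np.asarray(dmats, dtype=float)
    if d.ndim != 3 or d.shape[1] != d.shape[2]:
        raise ValueError("malformed distance matrices")
    n, L = d.shape[0], d.shape[1]
    mid = L // 2
    central1 = d[:, mid - 1, mid]
    central2 = d[:, mid, mid - 1]
    sym = 0.5 * (d + np.swapaxes(d, 1, 2))
    intact = sym < bound_cutoff
    flipped = intact[:, :, ::-1]
    offsets = np.arange(-(L - 2), L - 1)
    counts = np.stack(
        [np.trace(flipped, offset=-k, axis1=1, axis2=2) for k in offsets],
        axis=1,
    )
    # tie-break preference: smaller |k| first, positive k before negative
    pref = np.lexsort((offsets < 0, np.abs(offsets)))
    best_pos = np.argmax(counts[:, pref], axis=1)
    best_k = offsets[pref][best_pos]
    maxc = counts.max(axis=1)

    labels = np.full(n, UNASSIGNED, dtype=object)
    is_d = (central1 > dissoc_cutoff) & (central2 > dissoc_cutoff) & (maxc < 2)
    labels[is_d] = "D"
    rest = ~is_d & (maxc > 0)
    zero = rest & (best_k == 0)
    labels[zero] = "H"
    if sequence.has_gc_core:
        native = sym[:, np.arange(L), L - 1 - np.arange(L)]
        broken = native >= bound_cutoff
        f4 = zero & (central1 < bound_cutoff) & (central2 < bound_cutoff)
        any_run = np.zeros(n, dtype=bool)
        for run in _terminal_at_runs(sequence):
            if len(run) >= 4:
                any_run |= broken[:, list(run)].all(axis=1)
        labels[f4 & any_run] = "F4"
    for mag in (2, 4):
        labels[rest & (best_k == mag)] = f"5S{mag}"
        labels[rest & (best_k == -mag)] = f"3S{mag}"
    return labels


# --------------------------------------------------------------------------
# Transition path theory on macrostate transition matrices
# --------------------------------------------------------------------------

def _check_sets(n, source, sink, disjoint=True):
    source = np.asarray(sorted(set(source)), dtype=np.int64)
    sink = np.asarray(sorted(set(sink)), dtype=np.int64)
    if len(source) == 0 or len(sink) == 0:
        raise ValueError("source and sink must be nonempty")
    if disjoint and set(source) & set(sink):
        raise ValueError("source and sink must be disjoint")
    if source.max() >= n or sink.max() >= n or min(source.min(), sink.min()) < 0:
        raise ValueError("state index out of range")
    return source, sink


def committor(P: np.ndarray, source, sink) -> np.ndarray:
    """Forward committor q+ (probability of reaching sink before source).

    Solves the discrete committor linear system with exact boundary
    conditions q+ = 0 on the source set and 1 on the sink set.  States
    unreachable from source and sink are flagged with a warning.
    """
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    source, sink = _check_sets(n, source, sink)
    q = np.zeros(n)
    q[sink] = 1.0
    interior = np.setdiff1d(np.arange(n), np.concatenate([source, sink]))
    if len(interior):
        A = np.eye(len(interior)) - P[np.ix_(interior, interior)]
        b = P[np.ix_(interior, sink)].sum(axis=1)
        try:
            q[interior] = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            warnings.warn(
                "states unreachable from source/sink; using least squares",
                stacklevel=2,
            )
            q[interior] = np.linalg.lstsq(A, b, rcond=None)[0]
    return q


def _reactive_flux_out_of_source(P, pi, source, qplus) -> float:
    """Total reactive A->B flux: success-weighted flux out of the source."""
    source = np.asarray(source, dtype=np.int64)
    return float((pi[source, None] * P[source, :] * qplus[None, :]).sum())


def net_flux(P: np.ndarray, pi: np.ndarray, source, sink) -> np.ndarray:
    """Net reactive flux matrix f+_ij = max(f_ij - f_ji, 0).

    Uses the reversible-chain relation q- = 1 - q+ for the backward
    committor.
    """
    P = np.asarray(P, dtype=float)
    pi = np.asarray(pi, dtype=float)
    qp = committor(P, source, sink)
    qm = 1.0 - qp
    f = (pi * qm)[:, None] * P * qp[None, :]
    np.fill_diagonal(f, 0.0)
    return np.clip(f - f.T, 0.0, None)


def pathway_fraction(model, source, sink, via) -> float:
    """Fraction of reactive A->B flux whose paths visit the ``via`` set.

    Computed from the committor-based flux decomposition: the flux carried
    by pathways avoiding ``via`` uses the committor of reaching the sink
    before ``source u via``; the via fraction is one minus its share of the
    total reactive flux.
    """
    P = np.asarray(model.P if hasattr(model, "P") else model, dtype=float)
    if hasattr(model, "pi_macro"):
        pi = np.asarray(model.pi_macro, dtype=float)
    elif hasattr(model, "pi"):
        pi = np.asarray(model.pi, dtype=float)
    else:
        evals, evecs = np.linalg.eig(P.T)
        pi = np.real(evecs[:, np.argmax(np.real(evals))])
        pi = np.abs(pi) / np.abs(pi).sum()
    n = P.shape[0]
    source, sink = _check_sets(n, source, sink)
    via = np.asarray(sorted(set(via)), dtype=np.int64)
    if len(via) == 0:
        return 0.0
    if set(via) & (set(source) | set(sink)):
        raise ValueError("via set must be disjoint from source and sink")
    qp = committor(P, source, sink)
    total = _reactive_flux_out_of_source(P, pi, source, qp)
    if total <= 0:
        raise ValueError("zero reactive flux between source and sink")
    q_avoid = committor(P, np.concatenate([source, via]), sink)
    avoid = _reactive_flux_out_of_source(P, pi, source, q_avoid)
    return float(np.clip(1.0 - avoid / total, 0.0, 1.0))


def mfpt(model, lag: float, source, sink) -> float:
    """Mean first-passage time (ns) from source to the sink set.

    Solves the fundamental-matrix linear system for the per-state mean
    first-passage step counts, scales by the lag, and averages over the
    source states under the stationary distribution restricted to them.
    Returns 0 when the source is contained in the sink.
    """
    P = np.asarray(model.P if hasattr(model, "P") else model, dtype=float)
    if hasattr(model, "pi_macro"):
        pi = np.asarray(model.pi_macro, dtype=float)
    elif hasattr(model, "pi"):
        pi = np.asarray(model.pi, dtype=float)
    else:
        pi = np.full(P.shape[0], 1.0 / P.shape[0])
    n = P.shape[0]
    source, sink = _check_sets(n, source, sink, disjoint=False)
    if set(source) <= set(sink):
        return 0.0
    live = np.setdiff1d(np.arange(n), sink)
    A = np.eye(len(live)) - P[np.ix_(live, live)]
    try:
        m_live = np.linalg.solve(A, np.ones(len(live)))
    except np.linalg.LinAlgError as exc:
        raise ValueError("sink unreachable from source") from exc
    if np.any(m_live < 0):
        raise ValueError("sink unreachable from source")
    m = np.zeros(n)
    m[live] = m_live * lag
    src = np.setdiff1d(source, sink)
    w = pi[src]
    if w.sum() <= 0:
        w = np.ones(len(src))
    return float((m[src] * w).sum() / w.sum())


def mfpt_matrix(model, lag: float) -> np.ndarray:
    """Pairwise single-state MFPT matrix (ns), zero on the diagonal."""
    P = np.asarray(model.P if hasattr(model, "P") else model, dtype=float)
    n = P.shape[0]
    out = np.zeros((n, n))
    for j in range(n):
        for i in range(n):
            if i != j:
                out[i, j] = mfpt(P, lag, [i], [j])
    return out


@dataclass
class PathwayReport:
    """Committors, net fluxes, MFPTs, and via-set flux fractions."""

    qplus: np.ndarray
    flux: np.ndarray
    total_flux: float
    fraction_via: dict
    mfpt_matrix: np.ndarray
    source: tuple
    sink: tuple


def pathway_report(model, source, sink, via_sets: dict) -> PathwayReport:
    """Full transition-path report between source and sink macrostate sets."""
    P = model.P
    pi = model.pi_macro
    qp = committor(P, source, sink)
    total = _reactive_flux_out_of_source(
        P, pi, np.asarray(sorted(set(source))), qp
    )
    fractions = {
        name: (pathway_fraction(model, source, sink, v) if len(v) else 0.0)
        for name, v in via_sets.items()
    }
    return PathwayReport(
        qplus=qp,
        flux=net_flux(P, pi, source, sink),
        total_flux=total,
        fraction_via=fractions,
        mfpt_matrix=mfpt_matrix(model, model.lag),
        source=tuple(sorted(set(source))),
        sink=tuple(sorted(set(sink))),
    )
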