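"""Nearest-neighbor free energies per macrostate and MSM comparison.

Maps each macrostate's pairing register onto a paired stretch of the
duplex, sums stack, initiation, symmetry and dangling-end terms from the
embedded parameter table, converts MSM stationary populations into relative
free energies via ``F = -k_B T ln P + C`` referenced to the hybridized
state, and tabulates the discrepancy ``ddF = dF_MSM - dF_NN``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import constants as C
from . import nn_params
from .duplex_synth import DuplexSequence

__all__ = [
    "NNParameterTable",
    "DEFAULT_NN_TABLE",
    "paired_run",
    "nn_free_energy",
    "free_energies_from_populations",
    "compare_msm_nn",
    "macrostate_thermo_table",
    "KCAL_TO_KJ",
    "R_KJ",
]

KCAL_TO_KJ = 4.184
#: molar gas constant, kJ/(mol K)
R_KJ = 8.31446261815324e-3

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class NNParameterTable:
    """Nearest-neighbor dH/dS parameter set with provenance strings."""

    stacks: dict = field(default_factory=lambda: dict(nn_params.WC_STACKS))
    initiation: dict = field(default_factory=lambda: dict(nn_params.INITIATION))
    symmetry: tuple = nn_params.SYMMETRY
    dangling_5: dict = field(default_factory=lambda: dict(nn_params.DANGLING_5))
    dangling_3: dict = field(default_factory=lambda: dict(nn_params.DANGLING_3))
    source: str = nn_params.TABLE_SOURCE
    version: str = nn_params.TABLE_VERSION

    def stack(self, top: str) -> tuple:
        """dH/dS of the WC stack with top-strand dinucleotide ``top``."""
        bottom = _COMP[top[0]] + _COMP[top[1]]
        key = f"{top}/{bottom}"
        if key in self.stacks:
            return self.stacks[key]
        rc = f"{_COMP[top[1]]}{_COMP[top[0]]}/{top[1]}{top[0]}"
        if rc in self.stacks:
            return self.stacks[rc]
        raise KeyError(f"unknown stack {key}")


DEFAULT_NN_TABLE = NNParameterTable()


def paired_run(sequence: DuplexSequence, label: str) -> tuple:
    """Strand-1 native-position interval (a, b) paired in the given state.

    For register offset k, strand-1 base i pairs strand-2 base
    ``L - 1 + k - i``; the run is the longest contiguous stretch of
    Watson-Crick-compatible positions at that offset.  For F4 the intact
    stretch is the central core plus the high-index terminal run (a
    symmetric modeling choice).
    """
    bases = sequence.bases
    L = len(bases)
    if label == "D":
        raise ValueError("D has no paired stretch")
    if label == "F4":
        if not sequence.has_gc_core:
            raise ValueError("F4 requires a central G:C core")
        return (L // 2 - 1, L - 1)
    k = C.REGISTER_OFFSET[label]
    ok = np.zeros(L, dtype=bool)
    for i in range(L):
        j = L - 1 + k - i
        if 0 <= j < L:
            ok[i] = bases[i] == _COMP[bases[j]]
    best, cur, start, best_start = 0, 0, 0, 0
    for i in range(L):
        if ok[i]:
            cur += 1
            if cur > best:
                best = cur
                best_start = start if cur > 1 else i
            if cur == 1:
                start = i
        else:
            cur = 0
    if best < 2:
        raise ValueError(f"no paired stretch for {label} on {bases}")
    return (best_start, best_start + best - 1)


def _dangling_terms(sequence, a, b, k, table):
    """Dangling dH/dS contributions at both duplex ends.

    Only the first unpaired base adjacent to each duplex end contributes;
    tail bases beyond it are inert (NN convention).
    """
    bases = sequence.bases
    L = len(bases)
    terms = []
    flagged_tails = 0
    # end with terminal pair (s1[a], s2[jb]); jb = L-1+k-a
    jb = L - 1 + k - a
    if a > 0:  # 5' dangling base on strand 1
        x, p = bases[a - 1], bases[a]
        terms.append(table.dangling_5[f"{x}{p}/.{_COMP[p]}"])
        if a > 1:
            flagged_tails += 1
    if jb < L - 1:  # 3' dangling base on strand 2
        x, p = bases[jb + 1], bases[jb]
        terms.append(table.dangling_3[f".{_COMP[p]}/{x}{p}"])
        if jb < L - 2:
            flagged_tails += 1
    # end with terminal pair (s1[b], s2[ja]); ja = L-1+k-b
    ja = L - 1 + k - b
    if b < L - 1:  # 3' dangling base on strand 1
        x, p = bases[b + 1], bases[b]
        terms.append(table.dangling_3[f".{_COMP[p]}/{x}{p}"])
        if b < L - 2:
            flagged_tails += 1
    if ja > 0:  # 5' dangling base on strand 2
        x, p = bases[ja - 1], bases[ja]
        terms.append(table.dangling_5[f"{x}{p}/.{_COMP[p]}"])
        if ja > 1:
            flagged_tails += 1
    return terms, flagged_tails


def nn_free_energy(
    sequence: DuplexSequence,
    label: str,
    T: float,
    params: NNParameterTable = DEFAULT_NN_TABLE,
) -> float:
    """Nearest-neighbor duplex-formation free energy dG (kcal/mol) at T (K).

    Sums stack terms wholly inside the paired stretch implied by the
    state's register (or fraying pattern for F4), initiation terms for the
    two duplex-end pair classes, the symmetry correction when the paired
    duplex is self-complementary, and one dangling-end term per duplex end.
    ``label = "D"`` returns 0 (the unbound reference).  States with inert
    tails beyond the dangling base receive no tail penalty; they are
    flagged with a warning because the NN model is known to be deficient
    there.
    """
    if T <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    if label == "D":
        return 0.0
    bases = sequence.bases
    L = len(bases)
    a, b = paired_run(sequence, label)
    k = 0 if label == "F4" else C.REGISTER_OFFSET[label]
    dH = 0.0
    dS = 0.0
    for i in range(a, b):
        h, s = params.stack(bases[i: i + 2])
        dH += h
        dS += s
    for end in (a, b):
        cls = "G/C" if bases[end] in "GC" else "A/T"
        h, s = params.initiation[cls]
        dH += h
        dS += s
    # symmetry correction applies when the paired duplex is itself
    # self-complementary (always true for the symmetric registers of
    # identical strands, never for the asymmetric F4 stretch)
    seg1 = bases[a: b + 1]
    if seg1 == "".join(_COMP[c] for c in reversed(seg1)):
        h, s = params.symmetry
        dH += h
        dS += s
    terms, flagged = _dangling_terms(sequence, a, b, k, params)
    for h, s in terms:
        dH += h
        dS += s
    if flagged:
        warnings.warn(
            f"state {label}: {flagged} inert tail(s) beyond the dangling "
            "base carry no NN term (known NN-model deficiency)",
            stacklevel=2,
        )
    return dH - T * dS / 1000.0


def free_energies_from_populations(
    pi_macro: dict, T: float, reference: str = "H"
) -> dict:
    """Relative free energies dF(s) = -R T ln(pi_s / pi_ref) in kJ/mol."""
    if T <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    if reference not in pi_macro or pi_macro[reference] <= 0:
        raise ValueError(f"reference state {reference!r} has no population")
    out = {}
    for s, p in pi_macro.items():
        if p is None or p <= 0:
            warnings.warn(
                f"state {s} has zero/missing population; omitted",
                stacklevel=2,
            )
            continue
        out[s] = float(-R_KJ * T * np.log(p / pi_macro[reference]))
    return out


def compare_msm_nn(msm_col: dict, nn_col: dict, T: float) -> pd.DataFrame:
    """Aligned dF table with ddF = dF_MSM - dF_NN (kJ/mol) per state.

    Mismatched state sets are reduced to their intersection with a warning.
    """
    shared = [s for s in msm_col if s in nn_col]
    missing = set(msm_col) ^ set(nn_col)
    if missing:
        warnings.warn(
            f"state sets differ; using intersection (dropped {sorted(missing)})",
            stacklevel=2,
        )
    rows = []
    for s in shared:
        rows.append({
            "state": s,
            "dF_msm_kJ": msm_col[s],
            "dF_nn_kJ": nn_col[s],
            "ddF_kJ": msm_col[s] - nn_col[s],
            "T_K": T,
        })
    return pd.DataFrame(rows)


def macrostate_thermo_table(
    sequence: DuplexSequence,
    pi_macro: dict,
    T: float,
    params: NNParameterTable = DEFAULT_NN_TABLE,
) -> pd.DataFrame:
    """MSM-vs-NN free-energy comparison referenced to H, in kJ/mol."""
    msm = free_energies_from_populations(pi_macro, T)
    g_h = nn_free_energy(sequence, "H", T, params)
    nn = {}
    for s in pi_macro:
        if s == "D":
            nn[s] = (0.0 - g_h) * KCAL_TO_KJ
        else:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    nn[s] = (nn_free_energy(sequence, s, T, params) - g_h) * KCAL_TO_KJ
            except (ValueError, KeyError):
                continue
    return compare_msm_nn(msm, nn, T)
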