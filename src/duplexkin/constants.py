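"""Ground-truth constants for the synthetic duplex trajectory generator.

Every number that defines the synthetic kinetic networks, coordinate
templates, and noise processes lives here so the ground truth is inspectable
in one place.  Units are nm and ns throughout.

The preset rate networks are specified as symmetrized equilibrium fluxes
``s_ij = pi_i * q_ij`` (1/ns), which makes detailed balance hold by
construction: the generator converts them to rates via ``q_ij = s_ij / pi_i``.

Printed constraints honoured by the numbers below:

* every named preset places exactly half its stationary mass on the
  dissociated state D (melting conditions, u = 0);
* the AT-all preset places exactly 10.0% of its stationary mass on the four
  out-of-register shifted states, the GC-end preset 0.23% (split evenly
  across its three shifted states);
* the slowest relaxation timescale of every preset chain is ~1.0 us in
  generator units (1076 / 1098 / 1081 / 1000 ns for AT-all / GC-end /
  GC-core / GC-mix), i.e. equal across presets to well within 20%;
* starting from D, the AT-all flux into the shifted-state block is 2.2x the
  direct flux into H; the GC-end 5S4 state exchanges only with D (kinetic
  trap); the GC-core F4 state is short-lived (~55 ns) relative to H and D
  and relays most of the H<->D flux.
"""

from __future__ import annotations

# --------------------------------------------------------------------------
# Sequences (written 5'->3'; all four are self-complementary decamers)
# --------------------------------------------------------------------------
PRESET_SEQUENCES = {
    "AT-all": "ATATATATAT",
    "GC-end": "GATATATATC",
    "GC-core": "ATATGCATAT",
    "GC-mix": "ATGATATCAT",
}

SEQ_LENGTH = 10

# Register offset (in bases, along the ladder axis applied to strand 2) per
# macrostate label.  Positive offsets produce 5' overhangs, negative 3'.
REGISTER_OFFSET = {
    "H": 0,
    "5S2": +2,
    "3S2": -2,
    "5S4": +4,
    "3S4": -4,
    "F4": 0,
    "D": 0,
}

MACROSTATE_LABELS = ("H", "5S2", "3S2", "5S4", "3S4", "F4", "D")

# Macrostate sets per named preset, in canonical order.
PRESET_STATES = {
    "AT-all": ("H", "5S2", "3S2", "5S4", "3S4", "D"),
    "GC-end": ("H", "5S2", "3S2", "5S4", "D"),
    "GC-core": ("H", "F4", "D"),
    "GC-mix": ("H", "D"),
}

# --------------------------------------------------------------------------
# Stationary laws at u = 0 (melting conditions)
# --------------------------------------------------------------------------
_GC_END_SHIFTED = 0.0023 / 3.0  # 0.23% total, even three-way split

PRESET_STATIONARY = {
    "AT-all": {
        "H": 0.400,
        "5S2": 0.035,
        "3S2": 0.025,
        "5S4": 0.025,
        "3S4": 0.015,
        "D": 0.500,
    },
    "GC-end": {
        "H": 0.5 - 0.0023,
        "5S2": _GC_END_SHIFTED,
        "3S2": _GC_END_SHIFTED,
        "5S4": _GC_END_SHIFTED,
        "D": 0.500,
    },
    "GC-core": {"H": 0.45, "F4": 0.05, "D": 0.500},
    "GC-mix": {"H": 0.500, "D": 0.500},
}

# --------------------------------------------------------------------------
# Symmetrized equilibrium fluxes s_ij = pi_i q_ij (1/ns), upper triangle only.
# --------------------------------------------------------------------------
PRESET_FLUXES = {
    "AT-all": {
        ("H", "D"): 1.248e-4,
        ("5S2", "D"): 0.560e-4,
        ("3S2", "D"): 0.960e-4,
        ("5S4", "D"): 0.560e-4,
        ("3S4", "D"): 0.672e-4,
        ("H", "5S2"): 1.000e-4,
        ("H", "3S2"): 0.800e-4,
        ("5S2", "5S4"): 0.200e-4,
        ("3S2", "3S4"): 0.150e-4,
    },
    "GC-end": {
        ("H", "D"): 2.200e-4,
        ("5S2", "D"): 0.070e-4,
        ("3S2", "D"): 0.090e-4,
        ("5S4", "D"): 0.140e-4,  # trap: no 5S4 <-> H exchange
        ("H", "5S2"): 0.070e-4,
        ("H", "3S2"): 0.070e-4,
    },
    "GC-core": {
        ("H", "F4"): 7.500e-4,
        ("F4", "D"): 1.500e-4,
        ("H", "D"): 1.000e-4,
    },
    "GC-mix": {
        ("H", "D"): 2.500e-4,
    },
}

# Target slowest relaxation timescale of the preset chains (ns); tests assert
# each preset's leading eigen-timescale is within a factor 2 of this and that
# presets agree with one another within 20%.
HYBRIDIZATION_TIMESCALE = 1000.0

# Boundness potential used by the temperature factor u: rates are scaled as
# q_ij -> q_ij * exp(u * (b_i - b_j)), so every rate toward a less-bound
# state is amplified and its reverse attenuated, and detailed balance is
# re-established at pi_i' ~ pi_i * exp(-2 u b_i).
BOUNDNESS = {"H": 1.0, "5S2": 0.5, "3S2": 0.5, "5S4": 0.5, "3S4": 0.5,
             "F4": 0.5, "D": 0.0}

# --------------------------------------------------------------------------
# Coordinate templates and fast fluctuations
# --------------------------------------------------------------------------
# Straight antiparallel ladder: strand 1 base i at x = i*RISE; strand 2 base j
# at x = (SEQ_LENGTH-1-j+k)*RISE, y = PAIR_SEP for register offset k.  The
# rise is deliberately larger than B-DNA so that, with the 1.3 nm contact
# cutoff, one-base misalignments never register as intact contacts
# (sqrt(RISE^2 + PAIR_SEP^2) = 1.62 nm > 1.3 nm).
RISE = 1.5
PAIR_SEP = 0.6

# Dissociated template: strand separation along y (> 2.0 nm cutoff).
DISSOC_SEP = 3.5

# Mean-reverting (discrete AR(1)) coordinate jitter.
JITTER_SIGMA = 0.15
JITTER_CORR_TIME = 0.3

# Terminal-pair fraying: each duplex end toggles open/closed as a two-state
# jump process with total relaxation rate FRAY_TOGGLE_RATE and open
# probability FRAY_EQ_PROB; an open end displaces the two terminal bases by
# +-FRAY_DISP along z (pair distance sqrt(0.6^2 + 1.5^2) = 1.62 nm > 1.3 nm).
FRAY_TOGGLE_RATE = 1.0
FRAY_EQ_PROB = 0.25
FRAY_DISP = 0.75

# Classifier distance cutoffs (nm): intact-contact / dissociation.
BOUND_CUTOFF = 1.3
DISSOC_CUTOFF = 2.0
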