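"""Embedded nearest-neighbor thermodynamic parameters for DNA duplexes.

Unified oligonucleotide nearest-neighbor parameters (SantaLucia, PNAS 95:
1460-1465, 1998): per-stack hybridization enthalpies dH (kcal/mol) and
entropies dS (cal/(mol*K)) at 1 M NaCl, helix-initiation terms per terminal
pair class, and the symmetry correction for self-complementary duplexes.
Dangling-end terms from Bommarito, Peyret & SantaLucia (NAR 28:1929-1934,
2000).

Stack keys are written ``XY/ZW``: top strand 5'-XY-3' over bottom strand
3'-ZW-5'.  Dangling-end keys follow the same alignment with ``.`` marking
the absent partner, e.g. ``AA/.T`` is a 5' dangling A next to an A:T pair
and ``.A/AT`` a 3' dangling A next to an A:T pair.
"""

TABLE_SOURCE = (
    "SantaLucia 1998 unified NN parameters; "
    "Bommarito et al. 2000 dangling ends"
)
TABLE_VERSION = "unified-1998/dangling-2000"

# (dH kcal/mol, dS cal/mol/K)
WC_STACKS = {
    "AA/TT": (-7.9, -22.2),
    "AT/TA": (-7.2, -20.4),
    "TA/AT": (-7.2, -21.3),
    "CA/GT": (-8.5, -22.7),
    "GT/CA": (-8.4, -22.4),
    "CT/GA": (-7.8, -21.0),
    "GA/CT": (-8.2, -22.2),
    "CG/GC": (-10.6, -27.2),
    "GC/CG": (-9.8, -24.4),
    "GG/CC": (-8.0, -19.9),
}

# Helix initiation per duplex end, keyed by the terminal pair class.
INITIATION = {
    "G/C": (0.1, -2.8),
    "A/T": (2.3, 4.1),
}

# Self-complementary duplex symmetry correction.
SYMMETRY = (0.0, -1.4)

# 5' dangling ends: "XP/.Q" = dangling X 5' of paired base P (pair P:Q).
DANGLING_5 = {
    "AA/.T": (0.2, 2.3),
    "AC/.G": (-6.3, -17.1),
    "AG/.C": (-3.7, -10.0),
    "AT/.A": (-2.9, -7.6),
    "CA/.T": (0.6, 3.3),
    "CC/.G": (-4.4, -12.6),
    "CG/.C": (-4.0, -11.9),
    "CT/.A": (-4.1, -13.0),
    "GA/.T": (-1.1, -1.6),
    "GC/.G": (-5.1, -14.0),
    "GG/.C": (-3.9, -10.9),
    "GT/.A": (-4.2, -15.0),
    "TA/.T": (-6.9, -20.0),
    "TC/.G": (-4.0, -10.9),
    "TG/.C": (-4.9, -13.8),
    "TT/.A": (-0.2, -0.5),
}

# 3' dangling ends: ".Q/XP" = dangling X 3' of paired base P (pair P:Q).
DANGLING_3 = {
    ".A/AT": (-0.7, -0.8),
    ".A/CT": (4.4, 14.9),
    ".A/GT": (-1.6, -3.6),
    ".A/TT": (2.9, 10.4),
    ".C/AG": (-2.1, -3.9),
    ".C/CG": (-0.2, -0.1),
    ".C/GG": (-3.9, -11.2),
    ".C/TG": (-4.4, -13.1),
    ".G/AC": (-5.9, -16.5),
    ".G/CC": (-2.6, -7.4),
    ".G/GC": (-3.2, -10.4),
    ".G/TC": (-5.2, -15.0),
    ".T/AA": (-0.5, -1.1),
    ".T/CA": (4.7, 14.2),
    ".T/GA": (-4.1, -13.1),
    ".T/TA": (-3.8, -12.6),
}
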