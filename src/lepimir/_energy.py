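"""Bundled nearest-neighbor energy parameters.

A compact Turner-style parameter set: stacking free energies for all
Watson-Crick and G:U pair combinations (37 degC, kcal/mol) plus affine
penalties for hairpin, bulge, internal and multibranch loops.  Energies are
stored internally as integers in tenths of kcal/mol so the dynamic programs
can run on int32 arrays.
"""

from __future__ import annotations

import numpy as np

# base encoding
BASES = "ACGU"
ENC = {b: i for i, b in enumerate(BASES)}

# pair type codes: AU=0 UA=1 CG=2 GC=3 GU=4 UG=5, -1 = not pairable
PAIR_TYPES = ("AU", "UA", "CG", "GC", "GU", "UG")
PAIR_CODE = -np.ones((4, 4), dtype=np.int8)
for code, pt in enumerate(PAIR_TYPES):
    PAIR_CODE[ENC[pt[0]], ENC[pt[1]]] = code

# Stacking free energies, tenths of kcal/mol.  STACK[outer, inner] is the
# energy of pair `inner` stacked directly inside pair `outer` (5'->3').
# Watson-Crick values follow Xia et al.-style measurements; G:U values are
# representative wobble stacks.  All attractive except the weakest wobbles.
_S = {
    "AU": {"AU": -9, "UA": -11, "CG": -22, "GC": -21, "GU": -6, "UG": -14},
    "UA": {"AU": -13, "UA": -9, "CG": -24, "GC": -21, "GU": -10, "UG": -13},
    "CG": {"AU": -21, "UA": -21, "CG": -33, "GC": -24, "GU": -14, "UG": -21},
    "GC": {"AU": -24, "UA": -22, "CG": -34, "GC": -33, "GU": -15, "UG": -25},
    "GU": {"AU": -13, "UA": -14, "CG": -25, "GC": -21, "GU": -5, "UG": -4},
    "UG": {"AU": -10, "UA": -6, "CG": -15, "GC": -14, "GU": -3, "UG": -5},
}
STACK = np.zeros((6, 6), dtype=np.int32)
for i, po in enumerate(PAIR_TYPES):
    for j, pi in enumerate(PAIR_TYPES):
        STACK[i, j] = _S[po][pi]

# Affine loop penalties (tenths of kcal/mol).
MIN_HAIRPIN = 3          # minimum unpaired nt in a hairpin loop
HAIRPIN_A = 52           # hairpin loop of size 3
HAIRPIN_B = 2            # per extra unpaired nt
BULGE_A = 38             # bulge of size 1
BULGE_B = 2              # per extra unpaired nt
INTERNAL_A = 15          # internal loop base penalty
INTERNAL_B = 3           # per unpaired nt (total over both sides)
MULTI_A = 34             # multibranch loop closing penalty
MULTI_B = 4              # per branch (closing helix included)
MULTI_C = 1              # per unpaired nt inside the multiloop

MAXLOOP = 15             # max unpaired nt per side of an interior loop

INF = 1 << 28


def hairpin_penalty(size: int) -> int:
    return HAIRPIN_A + HAIRPIN_B * (size - MIN_HAIRPIN)


def bulge_penalty(size: int) -> int:
    return BULGE_A + BULGE_B * (size - 1)


def internal_penalty(size: int) -> int:
    return INTERNAL_A + INTERNAL_B * size
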