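"""Packaged reference values for the guava agroecosystem workflow.

These are field constants a user would otherwise retype: the mean chemical
analysis of dried-and-ground and fresh guava processing waste (dry-mass
basis), the locally recommended mineral fertilization, the default
sequential binary partition for foliar/fruit diagnosis, literature foliar
sufficiency ranges used to centre the synthetic generator, and molar masses
for charge-based soil unit conversions.

Units follow field convention: macronutrients in g kg⁻¹ dry mass,
micronutrients in mg kg⁻¹ dry mass (converted to g kg⁻¹ internally).
"""

from __future__ import annotations

import numpy as np

from .composition import SbpTable, sbp_to_basis

#: elements tracked in budget balance sheets
BUDGET_ELEMENTS = ("N", "P", "K", "Ca", "Mg", "S", "B", "Cu", "Fe", "Mn", "Zn")

#: macronutrient analyses in g kg⁻¹ dry mass
MACRO_ELEMENTS = ("N", "P", "K", "Ca", "Mg", "S")

#: micronutrient analyses in mg kg⁻¹ dry mass
MICRO_ELEMENTS = ("B", "Cu", "Fe", "Mn", "Zn")

# Guava-waste mean composition (dry-mass basis at 65 °C), multi-year means.
DRY_WASTE_MEAN = {
    "C": 289.0, "N": 12.2, "P": 2.20, "K": 2.42, "Ca": 0.86, "Mg": 0.96,
    "S": 1.26,                      # g kg⁻¹
    "B": 10.8, "Cu": 10.6, "Fe": 145.7, "Mn": 12.2, "Zn": 28.6,  # mg kg⁻¹
}
DRY_WASTE_SD = {
    "C": 15.2, "N": 1.02, "P": 0.19, "K": 0.22, "Ca": 0.09, "Mg": 0.05,
    "S": 0.11,
    "B": 1.84, "Cu": 1.14, "Fe": 9.5, "Mn": 1.3, "Zn": 1.8,
}
FRESH_WASTE_MEAN = {
    "C": 382.0, "N": 16.5, "P": 2.20, "K": 2.88, "Ca": 0.94, "Mg": 0.96,
    "S": 1.30,
    "B": 6.7, "Cu": 10.5, "Fe": 101.7, "Mn": 9.7, "Zn": 24.7,
}
FRESH_WASTE_SD = {
    "C": 5.09, "N": 0.58, "P": 0.16, "K": 0.08, "Ca": 0.13, "Mg": 0.11,
    "S": 0.07,
    "B": 1.8, "Cu": 1.1, "Fe": 5.5, "Mn": 1.1, "Zn": 1.8,
}

#: locally recommended mineral fertilization, kg element ha⁻¹ year⁻¹
#: (urea + ordinary superphosphate + KCl)
MINERAL_RECIPE = {"N": 229.0, "P": 12.5, "K": 71.4, "Ca": 31.5, "S": 19.0}

#: molar masses (g mol⁻¹) and charges for soil cation unit conversions
MOLAR_MASS = {"K": 39.098, "Ca": 40.078, "Mg": 24.305, "Na": 22.990}
CATION_CHARGE = {"K": 1, "Ca": 2, "Mg": 2, "Na": 1}

#: literature foliar sufficiency ranges for high-yield guava,
#: g kg⁻¹ dry mass (B in mg kg⁻¹); midpoints centre the synthetic generator
FOLIAR_SUFFICIENCY = {
    "N": (20.0, 23.0), "P": (1.4, 1.8), "K": (12.0, 17.0),
    "Ca": (7.0, 11.0), "Mg": (3.4, 4.0), "S": (2.5, 3.5), "B": (20.0, 25.0),
}

#: parts of the default diagnostic composition, in SBP column order
DIAGNOSTIC_PARTS = ("N", "P", "K", "Ca", "Mg", "S", "B", "Fv")

# Default SBP over six macronutrients, boron and the filling value.
# Fine-to-coarse: nutrient pairs first, then mobility contrasts, then the
# nutrient signal against the filling value.  Completing row
# [Ca,B | N,P,K,Mg,S] contrasts relatively immobile (Ca, B) with mobile
# nutrients and makes the design complete (7 balances for 8 parts) so the
# inverse transform and Monte-Carlo stages are well-posed.
_DEFAULT_SBP_CODES = np.array(
    [
        #  N   P   K  Ca  Mg   S   B  Fv
        [+1, -1,  0,  0,  0,  0,  0,  0],   # [P | N]
        [ 0,  0, +1,  0, -1,  0,  0,  0],   # [Mg | K]
        [-1, -1, +1,  0, +1,  0,  0,  0],   # [N,P | K,Mg]
        [+1, +1, +1,  0, +1, -1,  0,  0],   # [S | N,P,K,Mg]
        [+1, +1, +1, -1, +1, +1, -1,  0],   # [Ca,B | N,P,K,Mg,S]
        [ 0,  0,  0, +1,  0,  0, -1,  0],   # [B | Ca]
        [+1, +1, +1, +1, +1, +1, +1, -1],   # [Fv | N,P,K,Mg,S,Ca,B]
    ],
    dtype=int,
)

#: same design without the completing [Ca,B | …] row (forward ilr only)
_PARTIAL_SBP_CODES = np.delete(_DEFAULT_SBP_CODES, 4, axis=0)


def default_sbp(complete: bool = True) -> SbpTable:
    """The packaged diagnostic SBP (7 balances; 6 if ``complete=False``)."""
    codes = _DEFAULT_SBP_CODES if complete else _PARTIAL_SBP_CODES
    return SbpTable(DIAGNOSTIC_PARTS, codes.copy())


def default_basis(complete: bool = True):
    """Orthonormal basis of the packaged diagnostic SBP."""
    return sbp_to_basis(default_sbp(complete))
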