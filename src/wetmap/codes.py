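"""Land-cover class codes and subcategory groupings.

The delivery format labels the eight wetland subcategories with codes
180-187, non-wetland with 0 and ocean with 255.  Everything in the package
that touches labels goes through this module so that the code <-> name
mapping stays bijective and no other values are ever written.
"""

from __future__ import annotations

from enum import IntEnum


class ClassCode(IntEnum):
    """Wetland classification system codes.

    PWT permanent (inland) water, SWP swamp (woody inland), MSH marsh
    (herbaceous inland), FFT flooded flat, SLE saline, MGV mangrove,
    SMH salt marsh, TFT tidal flat; 0 is non-wetland, 255 ocean.
    """

    NWT = 0
    PWT = 180
    SWP = 181
    MSH = 182
    FFT = 183
    SLE = 184
    MGV = 185
    SMH = 186
    TFT = 187
    OCEAN = 255


#: All codes that may legally appear in a delivered annual label tile.
VALID_CODES = frozenset(int(c) for c in ClassCode)

#: The eight wetland subcategories (excludes non-wetland and ocean).
WETLAND_CODES = frozenset(
    int(c) for c in (ClassCode.PWT, ClassCode.SWP, ClassCode.MSH, ClassCode.FFT,
                     ClassCode.SLE, ClassCode.MGV, ClassCode.SMH, ClassCode.TFT)
)

CODE_TO_NAME = {int(c): c.name for c in ClassCode}
NAME_TO_CODE = {c.name: int(c) for c in ClassCode}

# Water-level-driven subcategory groups used by the temporal-consistency
# optimizer: a label flip inside a group reflects inundation state, not a
# land-cover change.  Inland permanent water (180) groups with flooded flat
# and marsh; ocean water (255) groups with tidal flat and salt marsh.
# Swamp, mangrove and saline remain singletons, as do non-wetland classes.
DEFAULT_GROUPS: tuple[frozenset[int], ...] = (
    frozenset({int(ClassCode.PWT), int(ClassCode.FFT), int(ClassCode.MSH)}),
    frozenset({int(ClassCode.TFT), int(ClassCode.SMH), int(ClassCode.OCEAN)}),
    frozenset({int(ClassCode.SWP)}),
    frozenset({int(ClassCode.MGV)}),
    frozenset({int(ClassCode.SLE)}),
    frozenset({int(ClassCode.NWT)}),
)


def validate_codes(values) -> list[int]:
    """Return the sorted list of illegal codes present in *values*.

    *values* is any integer array-like; an empty list means all codes are
    members of the delivery class set.
    """
    import numpy as np

    present = set(int(v) for v in np.unique(np.asarray(values)))
    return sorted(present - VALID_CODES)
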