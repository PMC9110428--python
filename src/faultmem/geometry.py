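"""Rake-angle geometry: fault categories, mirror reflections, boundary crossings.

Every stimulus is a geologic-fault animation characterised by a single rake
angle in degrees, measured anticlockwise from the horizontal on [0, 360).
The four prototypical fault categories tile the circle in overlapping
half-circles:

* reverse   — upward hanging-wall motion,  rake in (0, 180)
* normal    — downward hanging-wall motion, rake in (180, 360)
* left_lateral  — leftward motion,  rake in [0, 90) ∪ (270, 360)
* right_lateral — rightward motion, rake in (90, 270)

A generic angle therefore carries exactly two labels (one dip, one lateral);
the four cardinal angles 0/90/180/270 are pure prototypes with zero
displacement along the orthogonal dimension and carry exactly one label.
Category tests are done with exact comparisons in degrees, not with
``sin``/``cos`` signs, so grid angles like 90° are classified exactly.
"""

from __future__ import annotations

import enum
import math
from typing import Iterable

__all__ = [
    "FaultCategory",
    "BoundaryType",
    "normalize_angle",
    "circular_distance",
    "categorize",
    "mirror_swap_laterality",
    "mirror_swap_dip",
    "mirror_of",
    "crosses_boundary",
    "is_mirror_pair",
]


class FaultCategory(str, enum.Enum):
    NORMAL = "normal"
    REVERSE = "reverse"
    LEFT_LATERAL = "left_lateral"
    RIGHT_LATERAL = "right_lateral"


class BoundaryType(str, enum.Enum):
    """The two trained categorical distinctions."""

    LEFT_RIGHT = "left_right"
    NORMAL_REVERSE = "normal_reverse"


_DIP = frozenset({FaultCategory.NORMAL, FaultCategory.REVERSE})
_LATERAL = frozenset({FaultCategory.LEFT_LATERAL, FaultCategory.RIGHT_LATERAL})


def _boundary_pair(boundary: BoundaryType) -> frozenset:
    if boundary == BoundaryType.LEFT_RIGHT:
        return _LATERAL
    if boundary == BoundaryType.NORMAL_REVERSE:
        return _DIP
    raise ValueError(f"unknown boundary type: {boundary!r}")


def normalize_angle(angle: float) -> float:
    """Map any finite real angle (degrees) into [0, 360). Idempotent."""
    if not math.isfinite(angle):
        raise ValueError(f"rake angle must be finite, got {angle!r}")
    r = float(angle) % 360.0
    # tiny negative inputs round up to the modulus itself: (-1e-53) % 360
    return 0.0 if r >= 360.0 else r


def circular_distance(a: float, b: float) -> float:
    """Shortest arc between two angles in degrees, in [0, 180]."""
    d = abs(normalize_angle(a) - normalize_angle(b))
    return min(d, 360.0 - d)


def categorize(rake: float) -> frozenset:
    """Fault categories of a rake angle.

    Generic angles get one dip and one lateral label; cardinal angles
    (0, 90, 180, 270) get only their pure prototype.
    """
    r = normalize_angle(rake)
    cats = set()
    if 0.0 < r < 180.0:
        cats.add(FaultCategory.REVERSE)
    elif 180.0 < r < 360.0:
        cats.add(FaultCategory.NORMAL)
    if r < 90.0 or r > 270.0:
        cats.add(FaultCategory.LEFT_LATERAL)
    elif 90.0 < r < 270.0:
        cats.add(FaultCategory.RIGHT_LATERAL)
    # Cardinals fall through with exactly one label: 0 -> left, 90 -> reverse,
    # 180 -> right, 270 -> normal.
    return frozenset(cats)


def mirror_swap_laterality(rake: float) -> float:
    """Reflection that swaps left/right laterality: theta -> (180 - theta) mod 360.

    Preserves the dip (normal/reverse) label; involution.  This is the map
    behind the dashed "left/right mirror image" anti-diagonal.
    """
    return normalize_angle(180.0 - normalize_angle(rake))


def mirror_swap_dip(rake: float) -> float:
    """Reflection that swaps normal/reverse dip: theta -> (360 - theta) mod 360.

    Preserves the lateral label; involution.
    """
    return normalize_angle(360.0 - normalize_angle(rake))


def mirror_of(rake: float, axis: BoundaryType) -> float:
    """The mirror image of ``rake`` across the named categorical distinction."""
    if axis == BoundaryType.LEFT_RIGHT:
        return mirror_swap_laterality(rake)
    if axis == BoundaryType.NORMAL_REVERSE:
        return mirror_swap_dip(rake)
    raise ValueError(f"unknown boundary type: {axis!r}")


def crosses_boundary(mem: float, probe: float, boundary: BoundaryType) -> bool:
    """True iff memory and probe carry opposite labels of the boundary's pair.

    A stimulus at a cardinal angle lacks one of the two labels and therefore
    never crosses the orthogonal boundary.
    """
    pair = _boundary_pair(boundary)
    mem_label = categorize(mem) & pair
    probe_label = categorize(probe) & pair
    if not mem_label or not probe_label:
        return False
    return mem_label != probe_label


def is_mirror_pair(mem: float, probe: float, axis: BoundaryType, tol: float = 0.0) -> bool:
    """True iff ``probe`` is within ``tol`` degrees (circular) of the mirror of ``mem``."""
    if tol < 0:
        raise ValueError("tol must be >= 0")
    return circular_distance(probe, mirror_of(mem, axis)) <= tol
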