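"""Truncated-cone (frustum) geometry and metric unit conversions.

A stem section between two heights is approximated by a frustum with a
linear radius profile.  The lateral surface (base and top circles omitted)
gives the bark surface of the section; the frustum volume, evaluated over
and under bark, gives the bark volume by difference.  All geometry here is
in centimetres; conversions to and from mm/dm/m happen at module
boundaries via :func:`convert`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "DomainError",
    "Frustum",
    "frustum_lateral_surface",
    "frustum_volume",
    "convert",
]


class DomainError(ValueError):
    """An input lies outside the mathematical domain of an operation."""


@dataclass(frozen=True)
class Frustum:
    """A truncated cone: end radii ``r1``/``r2`` and length ``ls``, all in cm.

    ``r1`` is conventionally the bottom-end radius and ``r2`` the top-end
    radius, but nothing requires ``r1 >= r2``; both orders are valid and
    every derived quantity is symmetric under swapping the ends.  A zero
    radius (full cone, degenerate tip) is allowed; a non-positive length
    is not.
    """

    r1: float
    r2: float
    ls: float

    def __post_init__(self) -> None:
        if not self.ls > 0:
            raise DomainError(f"ls must be > 0, got ls={self.ls}")
        if self.r1 < 0:
            raise DomainError(f"r1 must be >= 0, got r1={self.r1}")
        if self.r2 < 0:
            raise DomainError(f"r2 must be >= 0, got r2={self.r2}")


def frustum_lateral_surface(f: Frustum) -> float:
    """Lateral surface area of a frustum in cm².

    ``S = pi * (r1 + r2) * sqrt((r1 - r2)^2 + ls^2)``; the areas of the
    base and top circles are omitted, matching the exposed bark surface
    of a stem section.
    """
    slant = math.hypot(f.r1 - f.r2, f.ls)
    return math.pi * (f.r1 + f.r2) * slant


def frustum_volume(f: Frustum) -> float:
    """Volume of a frustum in cm³: ``V = pi/3 * ls * (r1² + r1·r2 + r2²)``.

    Operands are ordered canonically so the result is bitwise identical
    under swapping the two ends.
    """
    a, b = sorted((f.r1, f.r2))
    return math.pi / 3.0 * f.ls * (a * a + a * b + b * b)


# Power-of-ten exponent of each length unit relative to the metre.
_LENGTH_EXP = {"mm": -3, "cm": -2, "dm": -1, "m": 0}
_AREA_EXP = {u + "2": e for u, e in _LENGTH_EXP.items()}


def _unit_exponent(unit: str) -> tuple[int, int]:
    """Return (decimal exponent, dimension) for a unit symbol.

    dimension is 1 for lengths, 2 for areas (``mm2`` .. ``m2``).
    """
    if unit in _LENGTH_EXP:
        return _LENGTH_EXP[unit], 1
    if unit in _AREA_EXP:
        return _AREA_EXP[unit], 2
    known = sorted(_LENGTH_EXP) + sorted(_AREA_EXP)
    raise DomainError(f"unknown unit {unit!r}; expected one of {known}")


def convert(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a length or area between metric units by exact powers of ten.

    Units are ``mm``, ``cm``, ``dm``, ``m`` and their squares ``mm2`` ..
    ``m2``.  Lengths cannot be converted to areas.  The scaling is a
    single multiplication or division by an exactly representable power
    of ten — one correctly-rounded operation, so a round trip returns
    the original value up to at most one unit in the last place (exact
    recovery of every double is impossible: scaling by ten needs more
    mantissa bits than the format has).
    """
    e_from, dim_from = _unit_exponent(from_unit)
    e_to, dim_to = _unit_exponent(to_unit)
    if dim_from != dim_to:
        raise DomainError(
            f"cannot convert between dimensions: {from_unit!r} -> {to_unit!r}"
        )
    diff = (e_from - e_to) * dim_from
    if diff == 0:
        return value
    if diff > 0:
        return value * (10.0 ** diff)
    return value / (10.0 ** -diff)
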