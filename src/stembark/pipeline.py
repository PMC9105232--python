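"""Per-section bark surface, volume, mass and specific surface mass.

Each vertical stem section (the standard profile is five 50 cm sections
from the ground to 2.5 m) is treated as a frustum whose end radii come
from the over-bark stem-radius model.  Bark volume is the difference
between the over-bark frustum and an inner frustum whose radii are
reduced by the bark thickness; mass follows from a user-supplied bark
density, and specific surface mass (SPH, g/dm²) is mass per unit of
outer surface — the quantity that converts a browsed bark area into a
forage mass.

Thickness convention: the thickness model is applied as a *radial*
allowance by default (inner radius = outer radius − Tb in cm).  Because
the field protocol derives thickness from over/under-bark *diameter*
differences, the alternative reading (inner radius = outer − Tb/2) is
available via ``thickness_convention="diameter"`` on every operation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .geometry import DomainError, Frustum, convert, frustum_lateral_surface, frustum_volume
from .models import (
    SpeciesModelLibrary,
    predict_bark_thickness,
    predict_height,
    predict_stem_radius,
)

__all__ = [
    "SectionSpec",
    "SectionBarkSummary",
    "STANDARD_SECTIONS",
    "THICKNESS_CONVENTIONS",
    "section_bark_surface",
    "section_bark_volume",
    "section_bark_mass",
    "specific_surface_mass",
    "profile",
]

#: ``"radial"``: Tb is a one-sided (radial) thickness; ``"diameter"``:
#: Tb is an over/under-bark diameter difference, i.e. twice the radial one.
THICKNESS_CONVENTIONS = ("radial", "diameter")

#: Floor (cm) at which the thickness power law is evaluated for a
#: section boundary at the ground, where the law itself is singular.
THICKNESS_HG_FLOOR_CM = 1.0


@dataclass(frozen=True)
class SectionSpec:
    """A vertical stem interval [lower, upper] in cm above ground."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not 0 <= self.lower < self.upper <= 250:
            raise DomainError(
                f"section must satisfy 0 <= lower < upper <= 250 cm, "
                f"got ({self.lower}, {self.upper})"
            )

    @property
    def length(self) -> float:
        return self.upper - self.lower


#: The published five-section profile of the bottom 2.5 m of the stem.
STANDARD_SECTIONS: tuple[SectionSpec, ...] = tuple(
    SectionSpec(lo, lo + 50.0) for lo in (0.0, 50.0, 100.0, 150.0, 200.0)
)


@dataclass(frozen=True)
class SectionBarkSummary:
    """Derived bark quantities for one stem section.

    ``bark_mass_g`` and ``specific_surface_mass_g_dm2`` are ``None``
    when no bark density was available.
    """

    section: SectionSpec
    surface_cm2: float
    bark_volume_cm3: float
    bark_mass_g: float | None = None
    specific_surface_mass_g_dm2: float | None = None


def _check_convention(thickness_convention: str) -> float:
    """Return the mm-of-thickness -> cm-of-radial-allowance factor."""
    if thickness_convention not in THICKNESS_CONVENTIONS:
        raise ValueError(
            f"thickness_convention must be one of {THICKNESS_CONVENTIONS}, "
            f"got {thickness_convention!r}"
        )
    # mm -> cm is /10; the diameter reading halves the radial allowance
    return 0.1 if thickness_convention == "radial" else 0.05


def _outer_radii(lib: SpeciesModelLibrary, d0: float, s: SectionSpec) -> tuple[float, float]:
    r1 = predict_stem_radius(lib.radius_model, d0, s.lower)
    r2 = predict_stem_radius(lib.radius_model, d0, s.upper)
    return float(r1), float(r2)


def section_bark_surface(lib: SpeciesModelLibrary, d0: float, s: SectionSpec) -> float:
    """Outer bark surface (cm²) of a section: frustum lateral surface."""
    r1, r2 = _outer_radii(lib, d0, s)
    return frustum_lateral_surface(Frustum(r1, r2, s.length))


def section_bark_volume(
    lib: SpeciesModelLibrary,
    d0: float,
    s: SectionSpec,
    thickness_convention: str = "radial",
) -> float:
    """Bark volume (cm³): over-bark frustum minus under-bark frustum.

    Thickness at each boundary is evaluated at ``max(hg, 1)`` cm because
    the thickness power law is singular at the ground.
    """
    factor = _check_convention(thickness_convention)
    r1, r2 = _outer_radii(lib, d0, s)
    t1 = predict_bark_thickness(
        lib.thickness_model, d0, max(s.lower, THICKNESS_HG_FLOOR_CM)
    )
    t2 = predict_bark_thickness(
        lib.thickness_model, d0, max(s.upper, THICKNESS_HG_FLOOR_CM)
    )
    inner1 = r1 - factor * t1
    inner2 = r2 - factor * t2
    if inner1 <= 0 or inner2 <= 0:
        raise DomainError(
            f"bark thicker than stem radius for {lib.species} at d0={d0} mm, "
            f"section ({s.lower}, {s.upper}): inner radii ({inner1:.4g}, {inner2:.4g}) cm"
        )
    outer = frustum_volume(Frustum(r1, r2, s.length))
    inner = frustum_volume(Frustum(inner1, inner2, s.length))
    return outer - inner


def section_bark_mass(
    lib: SpeciesModelLibrary,
    d0: float,
    s: SectionSpec,
    density_kg_m3: float | None = None,
    thickness_convention: str = "radial",
) -> float:
    """Oven-dry bark mass (g) of a section: volume × density.

    1 kg/m³ equals 1e-3 g/cm³, hence the conversion factor.
    """
    rho = density_kg_m3 if density_kg_m3 is not None else lib.bark_density
    if rho is None:
        raise ValueError(
            "bark density is not set: pass density_kg_m3 or build the library "
            "with a density (it is an external measurement, not part of the "
            "packaged models)"
        )
    vb = section_bark_volume(lib, d0, s, thickness_convention)
    return vb * rho * 1e-3


def specific_surface_mass(mass_g: float, surface_cm2: float) -> float:
    """Specific surface mass SPH (g/dm²) = bark mass / outer surface."""
    if surface_cm2 <= 0:
        raise DomainError(f"surface must be > 0 cm2, got {surface_cm2}")
    return mass_g / convert(surface_cm2, "cm2", "dm2")


def profile(
    lib: SpeciesModelLibrary,
    d0: float,
    density_kg_m3: float | None = None,
    max_height_cm: float = 250.0,
    sections: Sequence[SectionSpec] = STANDARD_SECTIONS,
    thickness_convention: str = "radial",
) -> list[SectionBarkSummary]:
    """Bark summaries along the stem, truncated at the predicted tree top.

    Sections above ``min(predicted height, max_height_cm)`` are dropped;
    a section containing the top is emitted partially with its true
    length, so totals do not lose stem.  Mass and SPH are filled only
    when a bark density is available (argument or library).
    """
    _check_convention(thickness_convention)
    rho = density_kg_m3 if density_kg_m3 is not None else lib.bark_density
    height_cm = float(predict_height(lib.height_model, d0)) * 100.0
    top = min(height_cm, max_height_cm)

    out: list[SectionBarkSummary] = []
    for s in sections:
        if s.lower >= top:
            continue
        clipped = s if s.upper <= top else SectionSpec(s.lower, top)
        surface = section_bark_surface(lib, d0, clipped)
        volume = section_bark_volume(lib, d0, clipped, thickness_convention)
        mass = sph = None
        if rho is not None:
            mass = volume * rho * 1e-3
            sph = specific_surface_mass(mass, surface)
        out.append(SectionBarkSummary(clipped, surface, volume, mass, sph))
    return out
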