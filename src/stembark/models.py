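"""Species-specific allometric models for young broadleaved stems.

Four model families link easily measured tree dimensions to bark-relevant
stem properties, each parameterised per species (common aspen, goat
willow, rowan, sycamore):

* tree height (m) from stem-base diameter ``D0`` (mm) via the rational
  form ``H = D0^2 / (b0 + b1*D0 + b2*D0^2)``, which saturates at ``1/b2``;
* diameter at breast height ``DBH`` (mm) from ``D0`` via a straight line;
* bark thickness ``Tb`` (mm) and stem radius ``r`` (cm) from ``D0`` (mm)
  and the height above ground ``Hg`` (cm) via the two-predictor power law
  ``b0 * D0^b1 * Hg^b2`` (``b1 > 0``, ``b2 < 0``: thicker/wider near the
  base of bigger trees, tapering upward).

The packaged coefficients were fitted to destructive samples of 600
young trees (stems sectioned to 2.5 m) and are transcribed at their
published precision; :func:`load_packaged_library` returns them per
species.  The power models are fitted only for the bottom 2.5 m of the
stem and for ``D0`` up to about 100 mm — predictions beyond that range
carry an :class:`ExtrapolationWarning`.
"""

from __future__ import annotations

import importlib.resources
import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Any, Mapping, Union

import numpy as np

from .geometry import DomainError

__all__ = [
    "SPECIES",
    "ExtrapolationWarning",
    "FitStatistics",
    "LinearModelCoefficients",
    "RationalHeightCoefficients",
    "PowerModelCoefficients",
    "PopulationStats",
    "SpeciesModelLibrary",
    "predict_height",
    "predict_dbh",
    "predict_bark_thickness",
    "predict_stem_radius",
    "load_packaged_library",
    "library_from_dict",
    "library_to_dict",
    "load_library_json",
]

#: Canonical species identifiers, in the packaged order.
SPECIES = ("common_aspen", "goat_willow", "rowan", "sycamore")

#: Fitted domain of the two-predictor power models.
D0_RANGE_MM = (5.0, 100.0)
HG_RANGE_CM = (0.0, 250.0)

ArrayLike = Union[float, np.ndarray]


class ExtrapolationWarning(UserWarning):
    """A prediction was requested outside the fitted data range."""


@dataclass(frozen=True)
class FitStatistics:
    """Goodness-of-fit summary of a regression model.

    ``mse`` is in squared response units; ``p_values`` maps coefficient
    names to two-sided p-values (floats for fitted models; printed
    strings such as ``"<0.001"`` for transcribed published models).
    """

    r_squared: float
    mse: float
    n: int | None = None
    p_values: Mapping[str, float | str] | None = None

    def __post_init__(self) -> None:
        if self.mse < 0:
            raise DomainError(f"mse must be >= 0, got {self.mse}")


@dataclass(frozen=True)
class LinearModelCoefficients:
    """``DBH = b0 + b1 * D0`` with both diameters in mm."""

    b0: float
    b1: float
    se_b0: float | None = None
    se_b1: float | None = None
    fit: FitStatistics | None = None

    def __post_init__(self) -> None:
        for name in ("se_b0", "se_b1"):
            se = getattr(self, name)
            if se is not None and not se > 0:
                raise DomainError(f"{name} must be > 0, got {se}")


@dataclass(frozen=True)
class RationalHeightCoefficients:
    """``H = D0^2 / (b0 + b1*D0 + b2*D0^2)``, H in m, D0 in mm.

    ``b2`` must be positive so the height saturates at the finite
    asymptote ``1/b2`` for large diameters.
    """

    b0: float
    b1: float
    b2: float
    se: Mapping[str, float] | None = None
    fit: FitStatistics | None = None

    def __post_init__(self) -> None:
        if not self.b2 > 0:
            raise DomainError(f"b2 must be > 0 for a finite height asymptote, got {self.b2}")

    @property
    def asymptotic_height(self) -> float:
        """Height limit (m) approached as D0 grows."""
        return 1.0 / self.b2


@dataclass(frozen=True)
class PowerModelCoefficients:
    """``y = b0 * D0^b1 * Hg^b2`` with D0 in mm, Hg in cm.

    ``response_unit`` is ``"mm"`` for bark thickness and ``"cm"`` for
    stem radius.
    """

    b0: float
    b1: float
    b2: float
    response_unit: str
    se: Mapping[str, float] | None = None
    fit: FitStatistics | None = None

    def __post_init__(self) -> None:
        if not self.b0 > 0:
            raise DomainError(f"b0 must be > 0, got {self.b0}")
        if self.response_unit not in ("mm", "cm"):
            raise DomainError(
                f"response_unit must be 'mm' or 'cm', got {self.response_unit!r}"
            )


@dataclass(frozen=True)
class PopulationStats:
    """Sample-population summary used to parameterise the simulator."""

    n_trees: int
    d0_mean_mm: float
    d0_sd_mm: float
    height_mean_m: float | None = None
    height_sd_m: float | None = None


@dataclass(frozen=True)
class SpeciesModelLibrary:
    """The four fitted models of one species, plus optional bark density.

    Bark density (oven-dry mass per fresh volume, kg/m³) is not part of
    the published model set and must be supplied by the user before mass
    or specific-surface-mass can be computed.
    """

    species: str
    dbh_model: LinearModelCoefficients
    height_model: RationalHeightCoefficients
    thickness_model: PowerModelCoefficients
    radius_model: PowerModelCoefficients
    bark_density: float | None = None
    population: PopulationStats | None = None

    def __post_init__(self) -> None:
        if self.bark_density is not None and not (50.0 < self.bark_density < 1500.0):
            raise DomainError(
                f"bark_density must lie in (50, 1500) kg/m3, got {self.bark_density}"
            )
        if self.thickness_model.response_unit != "mm":
            raise DomainError("thickness_model must have response_unit 'mm'")
        if self.radius_model.response_unit != "cm":
            raise DomainError("radius_model must have response_unit 'cm'")

    def with_density(self, bark_density: float) -> "SpeciesModelLibrary":
        """Return a copy with ``bark_density`` (kg/m³) set."""
        return replace(self, bark_density=bark_density)


def _validate_d0(d0: ArrayLike) -> np.ndarray:
    arr = np.asarray(d0, dtype=float)
    if np.any(arr <= 0):
        raise DomainError(f"d0 must be > 0 mm, got {d0}")
    return arr


def _maybe_scalar(x: np.ndarray, *inputs: ArrayLike) -> ArrayLike:
    if all(np.ndim(i) == 0 for i in inputs):
        return float(x)
    return x


def _warn_extrapolation(d0: np.ndarray, hg: np.ndarray) -> None:
    if np.any(d0 > D0_RANGE_MM[1]):
        warnings.warn(
            f"d0 beyond the fitted range (> {D0_RANGE_MM[1]:.0f} mm); "
            "the power models extrapolate",
            ExtrapolationWarning,
            stacklevel=3,
        )
    if np.any(hg > HG_RANGE_CM[1]):
        warnings.warn(
            f"hg beyond the fitted range (> {HG_RANGE_CM[1]:.0f} cm); "
            "the models were fitted only up to 2.5 m above ground",
            ExtrapolationWarning,
            stacklevel=3,
        )


def predict_height(m: RationalHeightCoefficients, d0: ArrayLike) -> ArrayLike:
    """Tree height (m) from stem-base diameter ``d0`` (mm)."""
    arr = _validate_d0(d0)
    denom = m.b0 + m.b1 * arr + m.b2 * arr * arr
    if np.any(denom <= 0):
        raise DomainError(
            f"height model denominator non-positive at d0={d0}; "
            "the model is invalid at this diameter"
        )
    return _maybe_scalar(arr * arr / denom, d0)


def predict_dbh(m: LinearModelCoefficients, d0: ArrayLike) -> ArrayLike:
    """Diameter at breast height (mm) from ``d0`` (mm).

    The fitted lines have negative intercepts, so small diameters give
    negative predictions; callers decide whether to clamp or drop them
    (physically such trees do not reach breast height).
    """
    arr = _validate_d0(d0)
    return _maybe_scalar(m.b0 + m.b1 * arr, d0)


def predict_bark_thickness(
    m: PowerModelCoefficients, d0: ArrayLike, hg: ArrayLike
) -> ArrayLike:
    """Bark thickness (mm) at height ``hg`` (cm) for a tree of ``d0`` (mm).

    The power law diverges as ``hg -> 0`` (``b2 < 0``); since no
    ground-level thickness measurement anchors a convention there,
    ``hg < 1`` cm is rejected rather than floored.
    """
    arr_d0 = _validate_d0(d0)
    arr_hg = np.asarray(hg, dtype=float)
    if np.any(arr_hg < 1.0):
        raise DomainError(
            f"hg must be >= 1 cm (power law singular at the ground), got {hg}"
        )
    _warn_extrapolation(arr_d0, arr_hg)
    out = m.b0 * arr_d0**m.b1 * arr_hg**m.b2
    return _maybe_scalar(out, d0, hg)


def predict_stem_radius(
    m: PowerModelCoefficients, d0: ArrayLike, hg: ArrayLike
) -> ArrayLike:
    """Over-bark stem radius (cm) at height ``hg`` (cm) for ``d0`` (mm).

    At ``hg = 0`` the power law is singular; there the radius is taken
    as half the measured stem-base diameter, ``d0 / 20`` (mm -> cm),
    which the fitted models approach within a few cm of the ground.
    """
    arr_d0 = _validate_d0(d0)
    arr_hg = np.asarray(hg, dtype=float)
    if np.any(arr_hg < 0):
        raise DomainError(f"hg must be >= 0 cm, got {hg}")
    _warn_extrapolation(arr_d0, arr_hg)
    with np.errstate(divide="ignore"):
        power = m.b0 * arr_d0**m.b1 * np.where(arr_hg > 0, arr_hg, 1.0) ** m.b2
    out = np.where(arr_hg > 0, power, arr_d0 / 20.0)
    return _maybe_scalar(out, d0, hg)


# ---------------------------------------------------------------------------
# Coefficient library (de)serialization


_SCHEMA = "stembark-coefficients-v1"
_MODEL_KEYS = ("dbh", "height", "radius", "thickness")


def _schema_error(msg: str) -> ValueError:
    return ValueError(f"invalid coefficient document: {msg}")


def _fit_from_entry(entry: Mapping[str, Any], names: tuple[str, ...]) -> FitStatistics:
    return FitStatistics(
        r_squared=float(entry["r_squared"]),
        mse=float(entry["mse"]),
        n=entry.get("n"),
        p_values={k: entry["p"][k] for k in names} if "p" in entry else None,
    )


def _require(entry: Mapping[str, Any], model: str, names: tuple[str, ...]) -> None:
    if "coefficients" not in entry:
        raise _schema_error(f"model {model!r} lacks 'coefficients'")
    missing = [k for k in names if k not in entry["coefficients"]]
    if missing:
        raise _schema_error(f"model {model!r} lacks coefficients {missing}")
    for k in ("r_squared", "mse"):
        if k not in entry:
            raise _schema_error(f"model {model!r} lacks {k!r}")


def _species_from_entry(species: str, node: Mapping[str, Any]) -> SpeciesModelLibrary:
    for key in _MODEL_KEYS:
        if key not in node:
            raise _schema_error(f"species {species!r} lacks model {key!r}")

    dbh = node["dbh"]
    _require(dbh, "dbh", ("b0", "b1"))
    dbh_model = LinearModelCoefficients(
        b0=float(dbh["coefficients"]["b0"]),
        b1=float(dbh["coefficients"]["b1"]),
        se_b0=float(dbh["se"]["b0"]) if "se" in dbh else None,
        se_b1=float(dbh["se"]["b1"]) if "se" in dbh else None,
        fit=_fit_from_entry(dbh, ("b0", "b1")),
    )

    hgt = node["height"]
    _require(hgt, "height", ("b0", "b1", "b2"))
    height_model = RationalHeightCoefficients(
        b0=float(hgt["coefficients"]["b0"]),
        b1=float(hgt["coefficients"]["b1"]),
        b2=float(hgt["coefficients"]["b2"]),
        se={k: float(v) for k, v in hgt.get("se", {}).items()} or None,
        fit=_fit_from_entry(hgt, ("b0", "b1", "b2")),
    )

    power = {}
    for key, unit in (("radius", "cm"), ("thickness", "mm")):
        entry = node[key]
        _require(entry, key, ("b0", "b1", "b2"))
        declared = entry.get("response_unit", unit)
        if declared != unit:
            raise _schema_error(f"model {key!r} must have response_unit {unit!r}")
        power[key] = PowerModelCoefficients(
            b0=float(entry["coefficients"]["b0"]),
            b1=float(entry["coefficients"]["b1"]),
            b2=float(entry["coefficients"]["b2"]),
            response_unit=unit,
            se={k: float(v) for k, v in entry.get("se", {}).items()} or None,
            fit=_fit_from_entry(entry, ("b0", "b1", "b2")),
        )

    pop = None
    if "population" in node:
        pop = PopulationStats(
            n_trees=int(node["population"]["n_trees"]),
            d0_mean_mm=float(node["population"]["d0_mean_mm"]),
            d0_sd_mm=float(node["population"]["d0_sd_mm"]),
            height_mean_m=node["population"].get("height_mean_m"),
            height_sd_m=node["population"].get("height_sd_m"),
        )

    return SpeciesModelLibrary(
        species=species,
        dbh_model=dbh_model,
        height_model=height_model,
        thickness_model=power["thickness"],
        radius_model=power["radius"],
        population=pop,
    )


def library_from_dict(doc: Mapping[str, Any], species: str) -> SpeciesModelLibrary:
    """Build a :class:`SpeciesModelLibrary` from a coefficient document."""
    if doc.get("schema") != _SCHEMA:
        raise _schema_error(f"schema must be {_SCHEMA!r}, got {doc.get('schema')!r}")
    if "species" not in doc or species not in doc["species"]:
        available = sorted(doc.get("species", {}))
        raise KeyError(f"unknown species {species!r}; document has {available}")
    return _species_from_entry(species, doc["species"][species])


def library_to_dict(lib: SpeciesModelLibrary) -> dict[str, Any]:
    """Serialize one species library to the coefficient-document node form."""

    def entry(coefs: Mapping[str, float], se, fit: FitStatistics | None, **extra):
        node: dict[str, Any] = {"coefficients": dict(coefs)}
        if se:
            node["se"] = dict(se)
        if fit is not None:
            if fit.p_values:
                node["p"] = dict(fit.p_values)
            node["r_squared"] = fit.r_squared
            node["mse"] = fit.mse
            if fit.n is not None:
                node["n"] = fit.n
        node.update(extra)
        return node

    d, h = lib.dbh_model, lib.height_model
    t, r = lib.thickness_model, lib.radius_model
    dbh_se = (
        {"b0": d.se_b0, "b1": d.se_b1} if d.se_b0 is not None and d.se_b1 is not None else None
    )
    return {
        "dbh": entry({"b0": d.b0, "b1": d.b1}, dbh_se, d.fit),
        "height": entry({"b0": h.b0, "b1": h.b1, "b2": h.b2}, h.se, h.fit),
        "radius": entry(
            {"b0": r.b0, "b1": r.b1, "b2": r.b2}, r.se, r.fit, response_unit="cm"
        ),
        "thickness": entry(
            {"b0": t.b0, "b1": t.b1, "b2": t.b2}, t.se, t.fit, response_unit="mm"
        ),
    }


def load_library_json(path: str | Path, species: str) -> SpeciesModelLibrary:
    """Load a species library from a coefficient JSON file on disk."""
    with open(path) as fh:
        return library_from_dict(json.load(fh), species)


def _packaged_document() -> dict[str, Any]:
    text = (
        importlib.resources.files("stembark") / "data" / "species_coefficients.json"
    ).read_text()
    return json.loads(text)


def load_packaged_library(
    species: str, bark_density: float | None = None
) -> SpeciesModelLibrary:
    """Return the published coefficient bundle for one species.

    ``species`` is one of :data:`SPECIES`.  ``bark_density`` (kg/m³) is
    optional; it is required downstream only for bark mass and specific
    surface mass.
    """
    if species not in SPECIES:
        raise KeyError(f"unknown species {species!r}; valid names: {list(SPECIES)}")
    lib = library_from_dict(_packaged_document(), species)
    if bark_density is not None:
        lib = lib.with_density(bark_density)
    return lib
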