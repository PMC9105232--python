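"""Seeded synthetic stem populations mirroring the destructive sampling.

The generator emulates the field protocol that produced the packaged
models: per species, stem-base diameters are drawn from a truncated
normal matching the published sample mean/SD; tree height, DBH, stem
radii and bark thicknesses are generated from the allometric models
(the "generating truth") plus additive Gaussian noise whose default SDs
are the square roots of the published model MSEs.  Stems are cut into
equal sections (at least four per tree, none longer than 1 m) with
over- and under-bark diameters recorded at both ends and the middle of
each section, like the caliper protocol.

Every random draw flows from the config seed, so identical configs give
byte-identical output.  :func:`to_observation_tables` bridges the
simulated measurements back to the fitting module, keeping positions
with 1 <= hg <= 250 cm (the power models' domain; the stem-base reading
at hg = 0 is recorded but is the direct d0/2 measurement, not a point
on the power law).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import ObservationTable
from .models import (
    SpeciesModelLibrary,
    load_packaged_library,
    predict_dbh,
    predict_height,
)

__all__ = [
    "SimulationConfig",
    "SimulatedSection",
    "SimulatedTree",
    "simulate_population",
    "simulate_sections",
    "to_observation_tables",
    "synthetic_power_table",
    "synthetic_dbh_table",
    "write_population",
    "read_population",
]

#: protocol floors
MIN_SECTIONS = 4
MAX_SECTION_CM = 100.0
HEIGHT_FLOOR_M = 0.3
DBH_FLOOR_MM = 1.0
DIAMETER_GAP_FLOOR_MM = 0.2  # under-bark always at least this far below over-bark

_POSITIONS = ("lower", "middle", "upper")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one species' synthetic population.

    Noise SDs are on each response's original scale: height in m, DBH in
    mm, stem radius in cm, bark thickness in mm.  The published height
    MSEs are read as cm² (heights were measured to the cm), hence the
    /100 in the default below.
    """

    species: str
    n_trees: int
    d0_mean_mm: float
    d0_sd_mm: float
    generating_models: SpeciesModelLibrary
    noise_height_m: float
    noise_dbh_mm: float
    noise_radius_cm: float
    noise_thickness_mm: float
    d0_min_mm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees <= 0:
            raise ValueError(f"n_trees must be > 0, got {self.n_trees}")
        if self.d0_min_mm <= 0:
            raise ValueError(f"d0_min_mm must be > 0, got {self.d0_min_mm}")
        for name in ("noise_height_m", "noise_dbh_mm", "noise_radius_cm", "noise_thickness_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def for_species(
        cls, species: str, seed: int = 0, n_trees: int | None = None, **overrides
    ) -> "SimulationConfig":
        """Config with the published sample sizes, D0 statistics, and
        noise SDs equal to sqrt(published MSE) for each model."""
        lib = load_packaged_library(species)
        pop = lib.population
        assert pop is not None
        cfg = cls(
            species=species,
            n_trees=n_trees if n_trees is not None else pop.n_trees,
            d0_mean_mm=pop.d0_mean_mm,
            d0_sd_mm=pop.d0_sd_mm,
            generating_models=lib,
            noise_height_m=math.sqrt(lib.height_model.fit.mse) / 100.0,
            noise_dbh_mm=math.sqrt(lib.dbh_model.fit.mse),
            noise_radius_cm=math.sqrt(lib.radius_model.fit.mse),
            noise_thickness_mm=math.sqrt(lib.thickness_model.fit.mse),
            seed=seed,
        )
        return replace(cfg, **overrides) if overrides else cfg


@dataclass(frozen=True)
class SimulatedSection:
    """One stem section with caliper readings at lower/middle/upper.

    Diameters are in mm; each value stands for the mean of the two
    perpendicular caliper directions of the protocol.
    """

    lower_cm: float
    upper_cm: float
    hg_cm: tuple[float, float, float]
    d_over_mm: tuple[float, float, float]
    d_under_mm: tuple[float, float, float]


@dataclass(frozen=True)
class SimulatedTree:
    tree_id: str
    species: str
    d0_mm: float
    height_m: float
    dbh_mm: float | None  # absent for trees not reaching breast height
    sections: tuple[SimulatedSection, ...] = field(default=())


def _draw_d0(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.d0_sd_mm == 0:
        return np.full(cfg.n_trees, max(cfg.d0_mean_mm, cfg.d0_min_mm))
    a = (cfg.d0_min_mm - cfg.d0_mean_mm) / cfg.d0_sd_mm
    return stats.truncnorm.rvs(
        a, np.inf, loc=cfg.d0_mean_mm, scale=cfg.d0_sd_mm,
        size=cfg.n_trees, random_state=rng,
    )


def _power_eval(model, d0: float, hg: np.ndarray) -> np.ndarray:
    # raw power law, bypassing range warnings (the generator legitimately
    # evaluates above 2.5 m when laying out tall stems)
    return model.b0 * d0**model.b1 * np.where(hg > 0, hg, 1.0) ** model.b2


def simulate_sections(
    tree: SimulatedTree, cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[SimulatedSection, ...]:
    """Cut one stem into equal sections and measure diameters at three
    positions per section.

    The section count is ``max(4, ceil(stem_length_cm / 100))`` over the
    full stem, which enforces both protocol rules.  The over-bark
    diameter at height hg is twice the modeled radius (the direct d0/2
    reading at the base) plus measurement noise; the under-bark diameter
    subtracts twice the modeled bark thickness (evaluated at
    ``max(hg, 1)`` cm) with noise, and never comes closer than 0.2 mm to
    the over-bark value.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    length_cm = tree.height_m * 100.0
    n_sections = max(MIN_SECTIONS, math.ceil(length_cm / MAX_SECTION_CM))
    bounds = np.linspace(0.0, length_cm, n_sections + 1)

    radius_model = cfg.generating_models.radius_model
    thickness_model = cfg.generating_models.thickness_model
    sections = []
    for lo, up in zip(bounds[:-1], bounds[1:]):
        hg = np.array([lo, (lo + up) / 2.0, up])
        r_cm = _power_eval(radius_model, tree.d0_mm, hg)
        r_cm[hg == 0] = tree.d0_mm / 20.0  # base radius is a direct measurement
        d_over = 20.0 * r_cm + 20.0 * cfg.noise_radius_cm * rng.standard_normal(3)
        d_over = np.maximum(d_over, 0.3)
        tb = _power_eval(thickness_model, tree.d0_mm, np.maximum(hg, 1.0))
        d_under = d_over - 2.0 * tb + 2.0 * cfg.noise_thickness_mm * rng.standard_normal(3)
        d_under = np.clip(d_under, 0.05, d_over - DIAMETER_GAP_FLOOR_MM)
        sections.append(
            SimulatedSection(
                lower_cm=float(lo),
                upper_cm=float(up),
                hg_cm=tuple(map(float, hg)),
                d_over_mm=tuple(map(float, d_over)),
                d_under_mm=tuple(map(float, d_under)),
            )
        )
    return tuple(sections)


def simulate_population(cfg: SimulationConfig) -> list[SimulatedTree]:
    """Draw a full synthetic population of measured trees (seeded)."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    d0 = _draw_d0(cfg, rng)
    lib = cfg.generating_models
    heights = np.asarray(predict_height(lib.height_model, d0), dtype=float)
    heights = heights + cfg.noise_height_m * rng.standard_normal(cfg.n_trees)
    heights = np.maximum(heights, HEIGHT_FLOOR_M)

    trees: list[SimulatedTree] = []
    width = len(str(cfg.n_trees))
    for i in range(cfg.n_trees):
        dbh: float | None = None
        if heights[i] > 1.3:
            dbh = float(predict_dbh(lib.dbh_model, d0[i])) + cfg.noise_dbh_mm * float(
                rng.standard_normal()
            )
            dbh = max(dbh, DBH_FLOOR_MM)
        tree = SimulatedTree(
            tree_id=f"{cfg.species}_{i + 1:0{width}d}",
            species=cfg.species,
            d0_mm=float(d0[i]),
            height_m=float(heights[i]),
            dbh_mm=dbh,
        )
        tree = replace(tree, sections=simulate_sections(tree, cfg, rng))
        trees.append(tree)
    return trees


def to_observation_tables(
    trees: Sequence[SimulatedTree], thickness_convention: str = "radial"
) -> dict[str, ObservationTable]:
    """Convert simulated measurements to one fitting table per response.

    Radius responses are ``d_over / 20`` (mm diameter -> cm radius);
    thickness responses are half the over/under diameter difference
    under the default radial convention, or the full difference under
    ``thickness_convention="diameter"``.  Only positions with
    1 <= hg <= 250 cm enter the two-predictor tables.
    """
    if not trees:
        raise ValueError("empty population")
    if thickness_convention not in ("radial", "diameter"):
        raise ValueError(f"unknown thickness_convention {thickness_convention!r}")
    t_factor = 0.5 if thickness_convention == "radial" else 1.0

    height_rows, dbh_rows, pos_rows = [], [], []
    for t in trees:
        height_rows.append((t.tree_id, t.species, t.d0_mm, t.height_m))
        if t.dbh_mm is not None:
            dbh_rows.append((t.tree_id, t.species, t.d0_mm, t.dbh_mm))
        for s in t.sections:
            for hg, d_over, d_under in zip(s.hg_cm, s.d_over_mm, s.d_under_mm):
                if 1.0 <= hg <= 250.0:
                    pos_rows.append((t.tree_id, t.species, t.d0_mm, hg, d_over, d_under))

    height = pd.DataFrame(height_rows, columns=["tree_id", "species", "d0_mm", "response"])
    dbh = pd.DataFrame(dbh_rows, columns=["tree_id", "species", "d0_mm", "response"])
    pos = pd.DataFrame(
        pos_rows, columns=["tree_id", "species", "d0_mm", "hg_cm", "d_over_mm", "d_under_mm"]
    )
    radius = pos[["tree_id", "species", "d0_mm", "hg_cm"]].copy()
    radius["response"] = pos["d_over_mm"] / 20.0
    thickness = pos[["tree_id", "species", "d0_mm", "hg_cm"]].copy()
    thickness["response"] = (pos["d_over_mm"] - pos["d_under_mm"]) * t_factor

    out = {
        "height_m": ObservationTable(height, "height_m"),
        "radius_cm": ObservationTable(radius, "radius_cm"),
        "thickness_mm": ObservationTable(thickness, "thickness_mm"),
    }
    if len(dbh):
        out["dbh_mm"] = ObservationTable(dbh, "dbh_mm")
    return out


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def synthetic_power_table(
    model,
    response_kind: str,
    n: int,
    d0_mean_mm: float,
    d0_sd_mm: float,
    seed,
    d0_min_mm: float = 5.0,
    hg_range_cm: tuple[float, float] = (1.0, 250.0),
    noise_sd: float = 0.0,
) -> ObservationTable:
    """Observations drawn directly from a two-predictor power model.

    D0 is truncated-normal, Hg uniform over ``hg_range_cm``, and the
    response is the model value plus zero-truncated Gaussian noise
    (measured radii and thicknesses are positive, so the Gaussian is
    resampled below zero; for typical signal-to-noise this shifts the
    mean by far less than one published standard error).
    ``response_kind`` is ``"radius_cm"`` or ``"thickness_mm"``.
    """
    rng = _as_rng(seed)
    if d0_sd_mm > 0:
        a = (d0_min_mm - d0_mean_mm) / d0_sd_mm
        d0 = stats.truncnorm.rvs(
            a, np.inf, loc=d0_mean_mm, scale=d0_sd_mm, size=n, random_state=rng
        )
    else:
        d0 = np.full(n, max(d0_mean_mm, d0_min_mm))
    hg = rng.uniform(hg_range_cm[0], hg_range_cm[1], n)
    mu = model.b0 * d0**model.b1 * hg**model.b2
    if noise_sd > 0:
        lo = -mu / noise_sd
        y = stats.truncnorm.rvs(lo, np.inf, loc=mu, scale=noise_sd, random_state=rng)
    else:
        y = mu
    df = pd.DataFrame(
        {
            "tree_id": [f"syn_{i}" for i in range(n)],
            "species": "synthetic",
            "d0_mm": d0,
            "hg_cm": hg,
            "response": y,
        }
    )
    return ObservationTable(df, response_kind)


def synthetic_dbh_table(
    lib: SpeciesModelLibrary,
    n: int,
    d0_mean_mm: float,
    d0_sd_mm: float,
    seed,
    d0_min_mm: float = 5.0,
    noise_sd: float = 0.0,
) -> ObservationTable:
    """DBH observations from the linear model for trees above breast height.

    D0 draws whose predicted height does not exceed 1.3 m are rejected
    (such trees carry no DBH), so exactly ``n`` usable trees remain.
    """
    rng = _as_rng(seed)
    a = (d0_min_mm - d0_mean_mm) / d0_sd_mm
    kept: list[float] = []
    while len(kept) < n:
        draw = stats.truncnorm.rvs(
            a, np.inf, loc=d0_mean_mm, scale=d0_sd_mm, size=2 * n, random_state=rng
        )
        heights = np.asarray(predict_height(lib.height_model, draw))
        kept.extend(draw[heights > 1.3].tolist())
    d0 = np.array(kept[:n])
    y = np.asarray(predict_dbh(lib.dbh_model, d0))
    if noise_sd > 0:
        y = y + noise_sd * rng.standard_normal(n)
    df = pd.DataFrame(
        {
            "tree_id": [f"syn_{i}" for i in range(n)],
            "species": lib.species,
            "d0_mm": d0,
            "response": y,
        }
    )
    return ObservationTable(df, "dbh_mm")


# ---------------------------------------------------------------------------
# CSV serialization (trees.csv + sections.csv)


def write_population(trees: Sequence[SimulatedTree], out_dir: str | Path) -> None:
    """Write ``trees.csv`` and ``sections.csv`` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tree_rows = [
        (t.tree_id, t.species, t.d0_mm, t.height_m, "" if t.dbh_mm is None else t.dbh_mm)
        for t in trees
    ]
    pd.DataFrame(
        tree_rows, columns=["tree_id", "species", "d0_mm", "height_m", "dbh_mm"]
    ).to_csv(out_dir / "trees.csv", index=False, float_format="%.17g")

    sec_rows = []
    for t in trees:
        for s in t.sections:
            for pos, hg, d_o, d_u in zip(_POSITIONS, s.hg_cm, s.d_over_mm, s.d_under_mm):
                sec_rows.append((t.tree_id, s.lower_cm, s.upper_cm, pos, hg, d_o, d_u))
    pd.DataFrame(
        sec_rows,
        columns=["tree_id", "lower_cm", "upper_cm", "position", "hg_cm", "d_over_mm", "d_under_mm"],
    ).to_csv(out_dir / "sections.csv", index=False, float_format="%.17g")


def read_population(in_dir: str | Path) -> list[SimulatedTree]:
    """Rebuild a population from ``trees.csv`` and ``sections.csv``."""
    in_dir = Path(in_dir)
    trees_df = pd.read_csv(in_dir / "trees.csv", float_precision="round_trip")
    sections_df = pd.read_csv(in_dir / "sections.csv", float_precision="round_trip")

    by_tree: dict[str, list[SimulatedSection]] = {}
    grouped = sections_df.groupby(["tree_id", "lower_cm", "upper_cm"], sort=False)
    for (tree_id, lo, up), grp in grouped:
        grp = grp.set_index("position").loc[list(_POSITIONS)]
        by_tree.setdefault(str(tree_id), []).append(
            SimulatedSection(
                lower_cm=float(lo),
                upper_cm=float(up),
                hg_cm=tuple(grp["hg_cm"].astype(float)),
                d_over_mm=tuple(grp["d_over_mm"].astype(float)),
                d_under_mm=tuple(grp["d_under_mm"].astype(float)),
            )
        )

    trees = []
    for row in trees_df.itertuples(index=False):
        dbh = None if pd.isna(row.dbh_mm) else float(row.dbh_mm)
        trees.append(
            SimulatedTree(
                tree_id=str(row.tree_id),
                species=str(row.species),
                d0_mm=float(row.d0_mm),
                height_m=float(row.height_m),
                dbh_mm=dbh,
                sections=tuple(by_tree.get(str(row.tree_id), ())),
            )
        )
    return trees
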