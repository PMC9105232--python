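# stembark

Bark thickness, surface area, volume and biomass along the stems of
young broadleaved trees.

Bark on young stems of common aspen (*Populus tremula*), goat willow
(*Salix caprea*), rowan (*Sorbus aucuparia*) and sycamore (*Acer
pseudoplatanus*) matters twice over: it is part of any honest tree
biomass or carbon budget, and it is the forage that red deer and other
large herbivores strip from exactly these species. `stembark` packages
species-specific allometric models for the bottom 2.5 m of the stem —
the part within browsing reach — and composes them into per-section
bark quantities, so that a measured stem-base diameter is enough to
estimate how much bark a tree carries and where.

The package is aimed at forest biometricians, wildlife ecologists and
biomass modellers who need reproducible bark estimates for small trees
(stem-base diameters roughly 5–100 mm), plus the simulation machinery
to validate the whole fitting chain.

## Models

All models use stem-base diameter *D₀* (mm) and, where relevant, the
height above ground *H_g* (cm):

- tree height (m): `H = D₀² / (b₀ + b₁·D₀ + b₂·D₀²)` — saturating at
  `1/b₂`;
- diameter at breast height (mm): `DBH = b₀ + b₁·D₀`;
- bark thickness (mm): `T_b = b₀ · D₀^b₁ · H_g^b₂`;
- stem radius over bark (cm): `r = b₀ · D₀^b₁ · H_g^b₂`.

Per 50 cm stem section (0–50, 51–100, …, 201–250 cm), radii at the
section ends feed the truncated-cone formulas

- surface: `S_b = π (r₁ + r₂) √((r₁ − r₂)² + l_s²)`,
- volume: `V = π/3 · l_s · (r₁² + r₁r₂ + r₂²)`,

bark volume is the over-bark minus the under-bark frustum
(`r_inner = r − T_b`), bark mass is `W_b = V_b · ρ_b` for a
user-supplied bark density `ρ_b` (kg/m³), and the specific surface
mass `SPH = W_b / S_b` (g/dm²) converts a browsed bark area directly
into a forage mass.

Fitted coefficients for all four species ship with the package
(`stembark.load_packaged_library`). Bark density does not — it is an
external measurement — and must be supplied before mass or SPH can be
computed.

## Worked example

```pycon
>>> import stembark as sb
>>> lib = sb.load_packaged_library("common_aspen", bark_density=480.0)
>>> round(sb.predict_bark_thickness(lib.thickness_model, 100.0, 50.0), 2)
4.52
>>> for s in sb.profile(lib, 100.0):
...     print(f"{s.section.lower:3.0f}-{s.section.upper:3.0f} cm  "
...           f"S={s.surface_cm2:7.1f} cm2  W={s.bark_mass_g:6.1f} g  "
...           f"SPH={s.specific_surface_mass_g_dm2:5.2f} g/dm2")
  0- 50 cm  S= 1376.8 cm2  W= 386.9 g  SPH=28.10 g/dm2
 50-100 cm  S= 1145.5 cm2  W= 222.9 g  SPH=19.46 g/dm2
100-150 cm  S= 1088.7 cm2  W= 195.8 g  SPH=17.99 g/dm2
150-200 cm  S= 1054.4 cm2  W= 180.6 g  SPH=17.13 g/dm2
200-250 cm  S= 1029.9 cm2  W= 170.1 g  SPH=16.52 g/dm2
```

A 100 mm aspen carries 4.5 mm of bark just above the ground — about
three times the sycamore value at the same point — and the bottom
half-metre of stem holds roughly twice the bark mass of any section
above it (the density of 480 kg/m³ here is illustrative, not a
packaged value). The same chain is available from the shell:

```sh
stembark report
stembark profile --species common_aspen --d0 100 \
    --density-kg-m3 common_aspen=480 --out profile.csv
stembark simulate --out-dir pop --seed 7      # synthetic measured trees
stembark fit --trees pop/trees.csv --sections pop/sections.csv --out coef.json
```

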