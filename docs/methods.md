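# Methods

## Model chain

`stembark` estimates bark properties of young broadleaved stems from a
single field measurement, the stem-base diameter *D₀* (mm), optionally
with the height above ground *H_g* (cm) of the point of interest. Four
regression families are packaged per species (common aspen, goat
willow, rowan, sycamore):

| model | form | response unit |
|---|---|---|
| height | `H = D₀²/(b₀ + b₁D₀ + b₂D₀²)` | m |
| DBH | `DBH = b₀ + b₁D₀` | mm |
| bark thickness | `T_b = b₀ D₀^{b₁} H_g^{b₂}` | mm |
| stem radius | `r = b₀ D₀^{b₁} H_g^{b₂}` | cm |

The rational height form rises like *D₀²* for small stems and
saturates at `1/b₂` — a finite asymptotic height — which is the
behaviour expected of a diameter–height curve without needing extra
parameters. The power laws carry a positive diameter exponent and a
negative height exponent for every packaged species: bark is thicker
and stems are wider on bigger trees, and both taper with height. All
packaged coefficients are kept at their published three-decimal
precision; standard errors, p-values (some only as printed upper
bounds such as `<0.001`), R² and MSE travel with them.

Per-section quantities treat a stem section between heights *h₁* and
*h₂* as a truncated cone with end radii from the radius model. The
lateral surface `S_b = π(r₁+r₂)√((r₁−r₂)²+l_s²)` deliberately omits
the end circles (they are not bark). Bark volume is the difference
between the over-bark frustum and an inner frustum whose radii are
reduced by the bark thickness at the matching heights; mass multiplies
by a bark density ρ_b (kg/m³); the specific surface mass
`SPH = W_b/S_b` (g/dm²) is the bark mass behind one square decimetre
of stem surface — the natural currency for converting a browsed patch
into a forage mass. In the thin-bark limit SPH reduces to ρ_b·T_b,
which anchors its magnitude independently of the geometry.

### Assumptions

- The radius profile between two measured heights is linear (frustum);
  taper curvature inside a 50 cm section is neglected. Away from the
  ground this costs well under 2% of a section's surface or volume
  (checked against quadrature in the tests).
- Bark density is constant along the 0–250 cm profile.
- The power models hold on the fitted domain only: D₀ up to about
  100 mm and H_g up to 250 cm. Beyond it, predictions are emitted with
  an `ExtrapolationWarning` rather than refused.

## Conventions at the domain edges

Three choices close gaps the model forms leave open; each is a
package-level convention, applied consistently and covered by tests.

**Ground-level radius.** The radius power law diverges at H_g = 0. The
stem-base radius is a direct field measurement, so `r(0) := D₀/20`
(half the base diameter, mm→cm). For packaged coefficients the fitted
law approaches this value within a few cm of the ground, so the splice
is mild — but it does make the near-ground profile non-linear, which
is why the 0–50 cm section is treated as a single frustum by
definition rather than as an approximation of a smooth solid.

**Ground-level thickness.** The thickness law also diverges at the
ground, and no direct base measurement anchors a convention there.
Thickness evaluation therefore *rejects* H_g < 1 cm; where a section
boundary sits at the ground, the pipeline evaluates thickness at the
1 cm floor. One centimetre is below the length resolution of any
sectioning protocol, so the floor does not interact with real
measurement positions.

**Radial vs. diameter thickness.** Field protocols derive thickness
from the difference of over- and under-bark *diameters*, which is
twice the one-sided (radial) thickness; the thickness model itself is
agnostic. The pipeline defaults to reading T_b as radial
(`r_inner = r − T_b`), because with plausible bark densities
(~400–500 kg/m³) this reproduces the reported SPH magnitudes
(~20 g/dm² for large aspen, ~7 g/dm² for sycamore), whereas the halved
allowance would require densities near 1000 kg/m³. The alternative is
available everywhere via `thickness_convention="diameter"`, and the
synthetic generator uses the same switch, so the choice cannot
silently diverge between generation and analysis.

## Fitting

The DBH line is ordinary least squares (statsmodels). The height and
power models are nonlinear least squares on the original response
scale (scipy `least_squares`), because the reported goodness-of-fit
values are mean squared errors in squared response units — a log–log
or transformed fit would minimise a different criterion. Both
nonlinear families are initialised from exact linearisations (OLS of
`D₀²/H` on `(1, D₀, D₀²)`; log–log OLS for the power law), which are
zero-residual optima for noiseless data, so noiseless closure holds to
machine precision.

Numerical choices:

- convergence: relative SSE change below 1e-12 (`ftol`), with a
  bounded evaluation budget; non-convergence raises, never returns
  silently;
- uncertainty: asymptotic covariance `s²(JᵀJ)⁻¹` with
  `s² = SSE/(n−k)`; two-sided Wald t p-values on `n−k` degrees of
  freedom;
- MSE is reported with the residual-degrees-of-freedom denominator
  `n−k` throughout;
- R² is `1 − SSE/SST`, reported as computed (it may be negative); a
  constant response with an essentially exact fit reports R² = 1, and
  otherwise zero total variance is an error;
- no weighting: residuals are treated as homoscedastic on the response
  scale.

## Synthetic populations

The generator emulates a destructive-sampling campaign so every stage
is testable without field data. Per species it draws *D₀* from a
normal distribution truncated at 5 mm, parameterised by the published
sample mean/SD (aspen 31.9/21.1 mm × 180 trees, willow 25.0/13.2 × 120,
rowan 36.7/21.4 × 100, sycamore 25.8/13.2 × 200); heights, DBH, radii
and thicknesses come from the packaged models plus additive Gaussian
noise whose default SDs are √MSE of each published fit. The published
height-model MSEs are plainly in cm² (heights of a few metres cannot
have residual variances of hundreds of m²; field height measurement is
to the cm), so the height noise default is √MSE/100 in metres
(≈0.35 m for aspen). Stems are cut into `max(4, ceil(length/1 m))`
equal sections; over- and under-bark diameters are generated at both
ends and the middle of each section, with the two perpendicular
caliper directions represented by their mean. Floors keep the output
physical: heights ≥ 0.3 m, DBH ≥ 1 mm (present only for trees above
1.3 m), over-bark diameters ≥ 0.3 mm, and the under-bark diameter at
least 0.2 mm below the over-bark one.

Observation tables for refitting keep positions with
1 cm ≤ H_g ≤ 250 cm: the base reading at H_g = 0 is the direct `D₀/2`
measurement (off the power-law curve by construction) and positions
above 250 cm are outside the fitted domain. For acceptance-style
parameter-recovery runs the package also generates observation tables
directly (no section structure): D₀ truncated-normal, H_g uniform on
[1, 250] cm, and zero-truncated Gaussian response noise — measured
radii and thicknesses are positive, so the Gaussian is resampled below
zero. At the default signal-to-noise this truncation shifts the
recovered exponents by far less than one published standard error.

What the generator does **not** emulate: stand structure and
competition, tree age (two stands of equal diameter but different age
are indistinguishable), operator and instrument error structure
(noise is i.i.d. Gaussian, real caliper errors are not), and any
correlation between the four response families beyond their shared
dependence on D₀. Passing recovery tests therefore demonstrate that
the fitting machinery is unbiased and consistent under the stated
noise model — not that the packaged models are correct for any
particular real stand.

A caveat worth stating plainly: at the published sample sizes the
sampling SD of the height-exponent estimates is comparable to or
larger than the published standard errors of those exponents (which
evidently derive from a larger or differently structured dataset than
the emulation reproduces). Recovery is therefore asserted on
replicate-set means, where it holds within three published standard
errors for every coefficient; single replicates scatter at the width
of that band.

## Known limitations

- No models above 250 cm or for stems beyond ~100 mm base diameter;
  whole-tree bark totals are out of reach by design.
- Branch bark is not modelled.
- Bark density must come from the user; the package refuses to invent
  one.
- Unit conversions are single correctly-rounded scalings by powers of
  ten; a convert-and-back round trip can differ from the input by one
  unit in the last place (exact recovery of every double is impossible
  when scaling by ten).
- The frustum lateral surface is not monotone in a radius for extreme
  geometries (length small against the radius gap); in the stem-section
  regime used here it is.
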