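# Methods

## Retention and conductivity model

The retention model treats the pore system as two lognormal pore-size
domains: a "textural" domain of fine matrix pores and a "structural"
domain of coarser inter-aggregate pores. Each domain contributes a
complementary-error-function drainage branch with median head h_m (cm)
and spread σ; the weight w apportions drainable pore space between them.
Heads are stored as positive suction magnitudes and pF = log10(h [cm]).
The conductivity curve is the Mualem closed form of the same mixture; it
satisfies K → Ks as h → 0 and K → 0 in the dry limit, and is evaluated
with `scipy.special.erfc`/`erfcinv`. Per-domain saturations that leave
[0, 1] by floating-point noise are clamped before the inverse-erfc step
(logged at debug level).

One naming caveat: h_m is sometimes loosely described as a median pore
*radius*; it enters the retention function as a median pressure *head*
and is implemented as such. The corresponding median radius is
0.149/h_m × 10⁴ μm via the capillary relation below.

## Fitting

Bounded trust-region least squares (`scipy.optimize.least_squares`) from
16 Latin-hypercube start points seeded with a fixed default (42,
recorded in the result). h_m and Ks are searched in log10. Bounds span
published mineral-soil ranges: θr ∈ [0, 0.25], θs ∈ [0.25, 0.65],
w ∈ [0.01, 0.99], h_m ∈ [1, 10⁵] cm, σ ∈ [0.1, 3.5],
Ks ∈ [10⁻³, 10⁴] cm d⁻¹, τ ∈ [−2, 3]. After the fit the two domains are
sorted so h_m1 ≤ h_m2 (label switching is otherwise unresolvable).
Datasets need ≥ 9 points spanning ≥ 2 decades of head.

The joint objective is Σ(θ residuals)² + λ·Σ(log10 K residuals)². The
default λ is the inverse-measurement-variance ratio (σθ/σlogK)² with
σθ = 0.003 cm³ cm⁻³ and σlogK = 0.1 (both exposed in `FitConfig`): each
residual block then contributes in proportion to its information
content, and noisy conductivity data cannot degrade the retention fit —
with per-point weighting (λ = nθ/nK, also available via `lambda_K`) the
conductivity block dominates and pushed retention RMSE an order of
magnitude above the noise floor in simulation. When no conductivity
data are provided, Ks and τ do not enter the objective and are reported
at placeholder values; they are non-identified from retention data
alone and are excluded from recovery tests.

Derived water points: field capacity at pF 1.8 and permanent wilting
point at pF 4.2, in vol-%; porosity φ = 1 − BD/ρs with particle density
ρs defaulting to 2.65 g cm⁻³ (standard mineral-soil value,
overridable). Dry-range (dew-point) measurements are merged into the
retention dataset before fitting; they receive no special treatment.

## Pore-size distributions and the structure index

The capillary (Young-Laplace) relation is implemented as
r [cm] = 0.149/h [cm] — the inverse form is forced by the physics and by
the index's own bounds (h = 1 cm ↔ r_max = 1490 μm; the wilting point
↔ r_min = 0.1 μm). Under this monotone map a lognormal head domain is a
lognormal radius component with the same σ, so the pore-size density
implied by a fitted curve is the two-component lognormal mixture with
medians 0.149/h_m·10⁴ μm, truncated to [r_min, r_max] and renormalized.
The density convention is d(Se)/dr — a proper probability density
independent of the (θs − θr) scale; the water-content-weighted
alternative dθ/dr differs only by that scale factor and coincides after
truncation-renormalization.

The reference (structureless) soil is built from the cumulative
particle-size distribution: equivalent pore radius = packing_factor ×
particle radius (default 0.3, configurable — this linear pore-to-grain
scaling is the module's largest approximation and the main caveat when
comparing absolute index values across studies), and cumulative mass
fraction F maps to water content θr + F·(θs_ref − θr), with θr taken
from the structured soil's fit and θs_ref = 0.30. The curve is extended
one decade past each end of the size range (where F is flat at 0 and 1)
so that even narrow textures give the fitter two decades of head span,
then refitted with the same bimodal form with θr and θs held fixed.

The KL divergence ∫ p ln(p/q) dr is integrated by adaptive quadrature on
the ln r axis (absolute tolerance 10⁻⁸, default bounds 0.1–1490 μm).
Results more negative than −10⁻⁸ raise; small negatives are clamped to
zero. A reference density that underflows to zero where the structured
density carries mass raises rather than silently flooring — the
divergence is genuinely infinite there.

## Aggregates and amendment accounting

Sand correction subtracts per-class sand mass before normalizing mass
fractions; the <53 μm class has no sand measurement and its sand mass is
fixed at zero. Replicate fractionations are corrected first and averaged
afterwards (robust to per-run input-mass differences). E_OC uses the OC
concentrations as measured on the fractions (a switch to sand-corrected
concentrations is deliberate future work; the raw convention is the
default because fraction OC is measured on the whole fraction).
Mass-weighted OC that differs from measured bulk OC by more than 15% is
flagged, not rejected (sieving-loss diagnostic); recovered mass more
than 2% above input mass is an error.

The dilution correction ships both Ĉ = C(1+B) (default, first-order
de-dilution) and exact de-mixing Ĉ = C/(1−B); they differ at O(B²),
about 1% of the correction at B = 0.10. Applications are summed
undepleted — no weathering-loss decay over the years. Rock sieve
classes map to aggregate classes with the 75 μm sieve equalized to the
53 μm aggregate boundary; per-class B values weighted by amended class
mass reproduce the bulk B exactly (tested to 10⁻¹²).

## Texture

The 12-class USDA/FAO triangle with half-open boundaries (lower bounds
inclusive), implemented as an if/else cascade that is total by
construction; totality and uniqueness are property-tested on a grid of
the simplex. Triplets summing to 100 ± 0.5 are renormalized with a log
note; larger discrepancies are errors.

## Statistics

Variables are z-scored with the sample (n−1) standard deviation.
Treatment comparisons use Kruskal-Wallis followed by Dunn's rank-based
post hoc z tests with tie correction, Holm-adjusted by default (the
adjustment is configurable — a reproducibility caveat, since different
adjustments change borderline letters). Compact letter displays use the
insert-absorb algorithm at α = 0.05; when the omnibus test is not
significant all groups share one letter. PCA runs on the z-scored table
via scikit-learn and equals a correlation-matrix PCA (tested against a
direct eigendecomposition). Dunn's statistics are assembled from scipy
primitives because no installed package exposes them.

## Synthetic data

The generator emulates a 3-treatment (control/basalt/lime) × 2-depth ×
3-block trial on a silt-loam soil. Truth hydraulic parameters resemble
such a soil (θs ≈ 0.50 at 1–6 cm, 0.45 at 15–20 cm; a structural domain
near h_m ≈ 60 cm and a textural domain near 2000 cm). Injected effects:
lime (and, weaker and shallower, basalt) adds coarse-domain weight
(+0.12 / +0.05 at the surface) so the structure index has signal;
pH/Ca shifts enter the chemistry; the silt-and-clay fraction's OC is
depleted at the surface (E_OC ≈ 0.86) and enriched at depth (≈ 1.12).
Noise: additive Gaussian on θ (sd 0.003, the evaporation-method error
scale), multiplicative lognormal on K (sd 0.1 in log10), cv-based
lognormal on OC (5%). Retention heads are log-spaced over pF 0–3.5 with
three dry-range points to pF 4.2, 60 points per sample in the trial
bundle (100-point pF 0–4.2 grids are used where only retention is
studied). All outputs are pure functions of (design, seed).

What passing tests on these data do *not* show: the generator draws
independent Gaussian/lognormal noise, has no instrument drift,
hysteresis, inter-variable correlation beyond the built-in effects, or
spatial field structure, so recovery and detection results bound
performance only under those idealized conditions.

## Problem sizes

The default test-suite trial uses one block (6 samples) and the
replicate fit checks use 20 replicates of 100 points — sizes chosen so
the full suite and the acceptance script each run in well under a few
minutes on a single CPU while still exercising every stage end to end.

## Known limitations

- The reference-soil construction (packing factor, linear size-to-pore
  map) is a documented approximation; absolute KL values depend on it,
  treatment contrasts much less so.
- Ks and τ are only identified when conductivity data are supplied.
- Whether reference densities should be water-content-weighted rather
  than normalized is an open convention; both are available and the
  normalized form is the default.
- The dilution mass balance ignores weathering losses of applied rock;
  over multi-year schedules it therefore slightly overstates B.
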