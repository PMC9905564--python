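# Methods

## Scope and data model

The package implements a census-based (ReefBudget-style) carbonate budget
for shallow, *Pocillopora*-dominated eastern-Pacific reefs, and its
conversion to reef-accretion potential (RAP) against localized sea-level
rise. All covers are proportions in [0, 1] internally; percentages appear
only in I/O tables and threshold reports. All bioerosion components are
stored as positive magnitudes; the negative sign conventionally printed on
erosion rates is applied only when formatting reports. This avoids
double-negation errors when summing components.

Surveys are point-intercept transects with a closed category vocabulary:
four coral taxa (*Pocillopora*, *Porites*, *Pavona*, *Gardineroseris*),
CCA, fine turf, thick turf, macroalgae, rubble, dead framework, and sand.
The "dead substrate" term D of the macroborer and urchin equations pools
dead framework and fine turf (configurable via the category mapping);
rubble is deliberately excluded from D because the sponge equation carries
its own rubble term, and counting it twice would inflate total bioerosion.

## Calcification

Dry skeletal weight from buoyant weight uses the hydrostatic identity
`W_d = W_b / (1 − ρ_sw/ρ_ar)` with defaults ρ_sw = 1.023 and
ρ_ar = 2.93 g cm⁻³ (both configurable; these are the conventional
hydrostatic-weighing values, distinct from the ambient-seawater density
1.03 g cm⁻³ used in the porosity correction). Interval rates standardize
ΔW_d by the mean of the start and end planar areas and by elapsed years
(365.25 d). A growth interval is assigned to a season by its midpoint
date; the default mapping labels March–September "non-upwelling" (the
higher-rate window) and October–February "upwelling". Regional usage of
these labels is not fully consistent, so the month→season map is a
parameter rather than a constant.

Aggregation averages within coral first, then across corals, so an
out-plant observed over several intervals contributes one value per group;
SE is the standard error of that group mean (reported as 0 with n = 1 for
singleton groups). Percent changes throughout the package use
`100 × (old − new)/old`, rounded half-up to an integer in report tables.

## Bioerosion components and defaults

Macroborer, urchin, sponge, pufferfish, and parrotfish equations are as in
the README. Default parameter values and their provenance:

- Microbioerosion 0.233 kg m⁻² yr⁻¹ is applied as a flat per-transect
  constant (the regional-database convention). An optional mode scales it
  by dead-substrate fraction for sensitivity analysis; whether the
  constant should apply to total or dead area is genuinely open, and the
  flat mode is the default because that is how the source figure is used.
- Sponge constants: prevalences 0.46 (live), 0.46 (rubble), 0.56
  (framework) and chemical dissolution 0.85 kg m⁻² yr⁻¹.
- Gulf-specific macroborer (ml, mt, md) and urchin (ul, ud, ut) rates are
  literature-derived site rates not re-measured here; the packaged
  defaults (GoP 6/30/35, GoC 2/30/15 kg m⁻² yr⁻¹; urchin rates ≈0.1/1.1/0.55
  and 0.1/1.0/0.5 g ind⁻¹ d⁻¹) were chosen so that the default synthetic
  cover trajectories yield gulf-mean macroboring and total-bioerosion
  magnitudes in the observed range (≈8 and ≈6.5 kg m⁻² yr⁻¹ macroboring;
  macroborers ≈85–90% of the total in both gulfs). They are configuration,
  not findings.
- Parrotfish per-capita erosion uses the ReefBudget structure
  (bites h⁻¹ × h d⁻¹ × 365 × scar fraction × scar volume × substrate
  density / 1000) with two *Scarus* species; fish densities surveyed in a
  single period are broadcast to all periods by an explicit fill step that
  flags extrapolated rows.
- Pufferfish: d_a = 17 g ind⁻¹ d⁻¹ with 0.6 of individuals feeding.

## Accretion potential

`ρ_x = C_x·D_f + (1 − C_x)·D_w` with D_f = 1.84 g cm⁻³ (wax-dip skeletal
density, SD ±0.20) and D_w = 1.03 g cm⁻³. Compaction summaries already
exclude the top ~2 m of open modern framework; the exclusion depth is
carried as metadata only. The RAP formula is implemented as
`RAP[mm yr⁻¹] = G[kg m⁻² yr⁻¹] / ρ[g cm⁻³] + S[mm yr⁻¹]`: a mass flux of
1 kg m⁻² yr⁻¹ of solid at ρ g cm⁻³ is a (1/ρ) mm yr⁻¹ thickness gain, so
no additional ×1000 appears in these units (a common source of confusion
when the intermediate is taken in meters; both readings are documented
here deliberately). Negative budgets yield negative RAP. The
millennial-scale variant replaces ρ_x by D_f; it is ≤ the full RAP only
where the budget is non-negative. Sediment contribution S is a per-site
configuration value (default 0 in the rate library; the synthetic study
uses 0.4 mm yr⁻¹, a mid-range value for these sheltered pocilloporid
reefs) because its derivation is outside the package's scope. Keep-up
classification is inclusive: RAP equal to the scenario rate counts as
keeping up (the boundary convention is arbitrary and documented).

## Threshold models and sea-level localization

Cover models are affine in percent cover with a gulf offset, fitted with
site random intercepts (statsmodels MixedLM, REML) and an automatic
fallback to OLS when only one site exists, the mixed fit fails, or the
between-site variance is negligible — threshold solving uses only the
fixed effects either way, so the fallback changes nothing downstream.
Thresholds are the linear inversion of the fixed effects at the target
rate; values above 100% cover are flagged unattainable rather than
clipped. Cover enters in percent so slopes are interpretable as response
units per percentage point.

Tide-gauge trends are OLS on decimal year over available months (missing
months omitted, never interpolated), with an annual sine/cosine pair
co-estimated by default. The harmonic is included because at monthly
sampling the seasonal cycle is not orthogonal to time: on a 50-year
synthetic series a 60-mm annual cycle aliases ≈0.05 mm yr⁻¹ into a plain
trend fit, a measurable bias relative to the ≈1.4 mm yr⁻¹ signal.
Localization multiplies a scenario's global rate by
`local_obs / global_obs`, with global_obs defaulting to the 20th-century
global-mean 1.7 mm yr⁻¹; the ratio may also be set directly.

## Synthetic study

The generator emulates the field design: 2 gulfs × 3 sites × 5 surveys
(spring/autumn 2016–2017, spring 2018) × 6 transects of 100 points, 20
out-plants per site measured at 6-month intervals, urchin video belts of
25 m² every period, fish belts of 100 m² in the final spring only, one
core summary per site, and a 50-year monthly tide-gauge record. Default
magnitudes: coral cover declining linearly 81→75% (GoP) and 51→39% (GoC);
true seasonal calcification 3.1/2.0 (GoP) and 2.9/2.3 (GoC)
g cm⁻² yr⁻¹; urchin densities rising 0.5→1.7 (GoP) and 0.4→4.9 (GoC)
ind m⁻²; compaction 0.62 ± 0.05; sea-level trend 1.4 mm yr⁻¹ with a 60-mm
annual harmonic, 30-mm monthly noise, and 2% of months missing.

Noise models are the simplest consistent with each data type: multinomial
points, Gaussian dry-weight increments (emitted as buoyant weights so the
estimator must invert the hydrostatic relation), Poisson belt counts,
Gaussian tide-gauge residuals. One integer seed drives all channels
through independently spawned substreams, so fixtures are byte-stable per
seed and channels are statistically independent. The generator does not
emulate spatial autocorrelation between transects, ENSO thermal events,
observer error in point classification, or coral partial mortality within
out-plants — so passing tests demonstrate correct inference under the
assumed sampling models, not robustness to those real-data features.

## Numerical choices

Budget additivity is enforced exactly (components are summed once; tests
check to 1e−12 relative). The `BudgetResult` container validates its
identities at 1e−9 to tolerate round-tripping through formatted CSV.
Output tables are written with fixed 6-decimal formatting so repeated runs
are byte-identical. Degenerate inputs fail loudly: zero-duration
intervals, non-positive densities/areas, compaction outside [0, 1],
constant cover in threshold fits, and zero slopes in threshold inversion
all raise rather than propagate NaN.

## Problem sizes

The test suite and acceptance script run the full default study design
(180 transects per run; 100-seed sweeps for the ordering checks, 12–20
seed sweeps for recovery checks, 50-year monthly tide records). These
sizes give sampling errors comfortably below the effect sizes being
checked while keeping a full run in well under a minute.

## Known limitations

Planar budgets (no rugosity) underestimate both production and erosion;
physical and chemical erosion are not modelled; the fitted thresholds
assume bioeroder assemblages stay at their surveyed state; RAP is a
maximum potential, not a predicted accretion rate; and the gulf-specific
borer/urchin rate defaults are literature stand-ins that users with local
measurements should override through the rate library.
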