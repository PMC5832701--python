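# Methods

`migrasim` estimates, for a set of migratory bird species, how far they must
fly between non-breeding and breeding ranges, how many refuelling stopovers
the journey requires, and how long it takes — under a present-day range
configuration and under a future configuration in which the two seasonal
ranges have shifted. This note records the model, its assumptions, the
defaults, and the choices made where the design was open.

## Flight mechanics

Mechanical power in level flapping flight is the classical three-component
fixed-wing decomposition:

* **Induced power** `P_ind = k (m g)^2 / (2 ρ V S_d)`, with induced power
  factor `k = 1.2` and disc area `S_d = π b² / 4` (`b` wing span, m).
* **Parasite power** `P_par = ½ ρ V³ S_b C_Db`, with body frontal area
  `S_b = 0.00813 m^0.666` (m in kg) and body drag coefficient `C_Db = 0.1`.
* **Profile power** `P_pro = (C_pro / AR) · P_am`, a speed-independent term
  proportional to the absolute minimum `P_am` of `P_ind + P_par`, with
  profile power constant `C_pro = 8.4` and aspect ratio `AR = b²/S`.

These are the standard textbook values of avian flight mechanics; all of
them are fields of `FlightParams`, so alternative calibrations are
configuration, not code changes. Basal metabolic power during flight is
deliberately omitted: it lengthens simulated ranges somewhat relative to
models that include it, and all downstream results here are comparative
(current vs. future under identical physiology), so the simplification
cancels where it matters. Soaring, wind and altitude-dependent density are
out of scope; flight is in still air at ρ = 1.17 kg m⁻³ (≈500 m).

**Speeds.** The minimum-power speed has the closed form
`V_mp = (a/3c)^¼` for `P_ind + P_par = a/V + cV³`. The maximum-range speed
`V_mr` minimises `P(V)/V` (the tangent from the origin to the power curve)
and is found by bounded scalar minimisation on `[V_mp, 20 V_mp]`; it always
exceeds `V_mp` for a U-shaped curve, which the tests assert.

**Fat conventions.** Fat load `F` is a fraction of all-up (laden) mass:
a bird of fat-free mass `m₀` departs at `m₁ = m₀ / (1 − F)`. Defaults:
`F = 0.30` before migration, `F = 0.20` when leaving a stopover — the
latter consistent with rebuilding fat for 5 days at 4% of fat-free mass
per day (`stopover_departure_fat` returns exactly this product, and the
constructor warns if rate × duration drifts from the configured stopover
fat load).

**Range integration.** `flight_range` marches in fixed 6-minute steps
(`step_seconds = 360`): at each step the bird flies at `V_mr` for its
current mass and converts fat to work at efficiency 0.23 against a fat
energy density of 3.9 × 10⁷ J kg⁻¹, until 95% of the initial fat load is
burned (the final step is fractionally truncated to land exactly on the
fuel budget). Halving the step changes range by < 0.1% (tested). A
`frozen_speed` mode holds speed and effective lift:drag at their initial
values, making the integral analytically equal to the Breguet range
`R = (η e / g)(L/D) ln(m₁/m₂)`; the suite uses it to verify the
integrator against the closed form within 2%. The reported `mean_speed`
is total distance over total airborne time — the single "typical speed"
reused for every leg of a journey, and the definition under which
`range = mean_speed × time` holds identically.

## Journeys, stopovers, duration

Journeys run non-breeding → breeding (spring, when birds are assumed to
travel as directly as possible). One journey samples an origin cell from
the non-breeding binary range and a destination cell from the breeding
binary range — each drawn with probability proportional to the cell's
climate suitability, independently across the (default 1000) replicates —
and flies the great-circle between the cell centres (haversine distance on
the R = 6371.0088 km sphere).

Stopovers: with pre-migration range `Y₀` and post-stopover range `Y₁`,
a journey of length `D` needs `0` stopovers if `D ≤ Y₀` and
`⌈(D − Y₀)/Y₁⌉` otherwise. A bird exactly at its maximum range has
arrived (boundary counts as reachable); equivalence with a leg-by-leg
simulation is asserted over 10⁴ random triples. Refuelling is assumed
possible wherever fuel runs out — sea crossings are not penalised and
barrier detours are not modelled, a documented limitation that biases
distances short for detouring species.

Duration sums four parts — initial flight, inter-stopover flights, final
flight, and stopover residence: flight hours `D / (3.6 · V̄)` are divided
by the daily flight window (9 h for nocturnal, 15 h for diurnal migrants)
and added to 5 days per stopover; fractional days are retained. Flight
days and stopover days are additive (no refuel-by-day/fly-by-night
overlap).

The journey corridor (central 90% band) interpolates each journey's
great-circle latitude at each 0.5° longitude via the standard
intermediate-point formula and takes pointwise 5th–95th percentiles;
longitudes no journey crosses are flagged, not errors. Purely meridional
journeys have a degenerate crossing and contribute only at their own
longitude.

## Range shifts and statistics

Suitability surfaces are converted to presence/absence either with a fixed
threshold (default 0.5) or, when a reference presence lattice is available,
with maxSSS — the threshold maximising sensitivity + specificity, the
standard prevalence-robust choice. The threshold used is recorded in the
output.

Range centres are the suitability-weighted mean of 1000 sampled presence
cells, averaged as unit vectors on the sphere and renormalised (correct
near the antimeridian; indistinguishable from planar averaging at
continental scale). Shift vectors are the haversine distance and initial
great-circle bearing between current and future centres. Bearings from
shifts under 1 km are excluded from circular tests.

Statistical layer:

* **Watson–Williams circular ANOVA** for equality of mean directions,
  with the high-concentration correction `1 + 3/(8κ̂)`, `κ̂` estimated
  from the pooled within-group mean resultant length by the standard
  maximum-likelihood approximation. The test warns (and flags its result)
  for `κ̂ < 2`. Calibration is verified empirically: type-I error within
  [0.03, 0.08] at α = 0.05 over 2000 null simulations, and rejection
  agreement with a permutation oracle on separated groups.
* **Paired t-tests** on per-species means (future − current), with an
  explicit degenerate flag when the differences have zero variance.
* **Slope-versus-unity regression**: OLS of future on current means with
  intercept; `t = (β̂ − 1)/se(β̂)` tests whether longer journeys change
  disproportionately. Numerically exact fits are detected and reported
  with `t = 0, p = 1` on the unity line.

## Validation against tracks

For a species with `n ≥ 6` tracked individuals, each of 1000 repeats draws
`n` simulated journeys without replacement and compares them with the
observations by a two-sided Mann–Whitney test (asymptotic with tie
correction — ties are routine for stopover counts; the repeats are
evaluated in one vectorised call). The mean U and mean p across repeats
are reported; `mean_p ≥ α` is "consistent", otherwise the sign of
(simulated − observed) mean labels the bias. Smaller samples raise an
error rather than returning an under-powered comparison.

## Synthetic data

The pipeline consumes only suitability surfaces, a trait table and track
summaries, so synthetic stand-ins exercise every downstream stage:

* **Traits**: fat-free mass log-uniform on [0.008, 0.3] kg; wing span
  `1.05 m^0.36` with 6% lognormal scatter; aspect ratio lognormal around 7
  clipped to [4.5, 12] — passerine-scale allometry. Strategy split is
  exactly the configured proportion (default 40 short- : 37 long-distance
  of 77); flight period is drawn per species (default 70% nocturnal).
* **Ranges**: single Gaussian blobs `peak · exp(−d²/2s²)` in great-circle
  distance `d` from a centre, on a 0.5° lattice over a Europe–Africa
  window (default 25° W–65° E, 35° S–72° N). Defaults: breeding blobs near
  (12° E, 52° N), scale 300 km; long-distance non-breeding blobs near
  (8° E, 2° N), scale 350 km; short-distance non-breeding blobs at the
  breeding longitude, 41° N. Per-species centres are jittered so current
  journey lengths spread over roughly 4500–6900 km (long) and
  900–1500 km (short), comparable to real Afro-Palaearctic and
  intra-European migrations. Real SDM output is patchier and multimodal;
  single blobs mean the synthetic tests validate the machinery, not the
  ecological realism of any particular species map.
* **Future scenarios** displace blob centres along a great-circle bearing.
  Long-distance defaults (breeding 12.3°/410 km, non-breeding
  69.8°/305 km) reproduce a divergent geometry in which journey ends move
  apart. The short-distance default is the control arm: both seasonal
  ranges shift 430 km due north along their shared meridian — an equal
  parallel displacement that preserves great-circle journey distance
  exactly (which a slanted parallel shift on a sphere does not, by a few
  km — detectable at Monte-Carlo precision), isolating sampling noise in
  the no-change scenario. Short-distance species therefore share one
  longitude jitter across seasons.
* **Tracks** subsample a simulated ensemble's metric, multiplied by a bias
  factor and mean-one lognormal noise of given CV — enough to emulate both
  agreeing geolocator data (bias 1) and detour-inflated observations
  (bias > 1).

## Reproducibility and problem sizes

All randomness flows from one top-level seed; per-species streams are
derived from the seed plus a CRC-32 of the species id, so per-species
results are independent of iteration order. Default experiment sizes —
77 species × 1000 journeys × 2 scenarios, 1000 validation repeats,
2000-replicate calibration nulls — run in well under a minute on one core
and are the sizes used throughout the test suite.

## Known limitations

Straight-line routes (no barriers, wind or detours); no protein
catabolism or muscle-mass dynamics; no basal metabolism in flight; land
availability for refuelling unchecked; single-blob synthetic ranges; the
Watson–Williams test assumes high concentration and von Mises-like
groups (flagged, not enforced).
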