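# Methods

## Model overview

`sahelsim` simulates *Anopheles gambiae* s.l. population dynamics as a
stochastic metapopulation on a network of human settlements inside a square
study region (default: 1000 km sides centred on −1.737°E, 12.274°N).  Every
settlement is a potential population site holding integer counts of
juveniles (all immature stages, egg to pre-reproductive adult, a fixed
T_L days), adult males, virgin females and mated females, plus a ledger of
aestivating mated females.  All counts are updated daily from pseudo-random
draws; time runs on a 365-day no-leap calendar (seasonal windows are
approximate, so leap-day bookkeeping would add complexity without
precision).

Daily event order (fixed; the underlying biology does not dictate one):

1. refresh α(x,t) at week boundaries;
2. juvenile survival and ageing — every age class survives with p_s
   computed from the pre-update juvenile total, survivors of age T_L leave
   the pool as emergers;
3. emergence — binomial male/virgin-female split;
4. adult survival (the newly emerged are exposed: females can mate and die
   on their first day, consistent with mating on the day of emergence);
5. mating, with p_m from the post-mortality male count;
6. aestivation — ledger release, then entry draws (the entry and emergence
   windows are disjoint by construction, so the order of release vs entry
   within the day is observationally irrelevant);
7. oviposition into juvenile age class 1;
8. movement: local dispersal first, then migration drawn from
   post-dispersal residents.

A settlement with zero individuals of every stage is absorbing unless it
receives immigrants.  Metapopulation-wide extinction ends a replicate early
with the day recorded on the result.

## Demography

* `p_s = [α/(α + J_T)]^(1/T_L) · (1 − μ_J)` — the density-dependent factor
  is scaled so that holding J_T = α over the whole development period
  gives exactly a 50% chance of death from larval competition, which makes
  α interpretable as a carrying-capacity scale in juvenile units.  μ_J is
  a per-day density-independent mortality applied inside p_s, exactly as
  the survival expression is written.
* `p_m = M/(β + M)` with β = 100 males, so mating is nearly certain on the
  first day in any but tiny populations (old virgin females are assumed
  rare).
* Mated females lay Poisson(θ) eggs per day; the per-settlement total is
  drawn as Poisson(θ·F) by superposition.
* Adults die with constant probability μ_A = 0.125 per day (exponential
  lifetimes).  An optional variant caps adult age at 30 days: adult arrays
  then carry an age dimension and survivors age daily, dying at the cap.
  The cap exists to check that the exponential tail (rare very old adults)
  does not drive the results; aestivating females re-enter at age 0 under
  the cap, a simplification documented here because dormancy physiology is
  outside the model.

## Habitat: α(x,t)

`α(x,t) = α₀(x) + α₁(1 − e^(−φ r(x,t))) + α₂(1 − e^(−κ[W_p + W_n(1 − e^(−δ r))]))`

* r(x,t): weekly total rainfall (mm/week) of the settlement's 0.5° grid
  cell — α therefore changes weekly, not daily.  Cell lookup is
  containing-cell only; no interpolation.
* W_p, W_n: km of perennial and non-perennial water course within
  L_w km of the settlement.  Polygon lakes contribute their boundary rings
  (peripheral breeding); lengths are measured by projecting segments onto
  a local tangent plane and intersecting with a disc (128 arcs/quadrant),
  which matches dense point-sampling within well under 1%.
* Heavy rain makes intermittent courses equivalent to perennial ones
  (checked as an identity in the tests).
* α₀(x): "small permanent larval sites", lognormal across settlements with
  *natural-scale* mean α₀^μ and variance α₀^σ² (the symbols are described
  as the mean and variance of the distribution, so the natural scale is
  the faithful reading; log-scale parameters are derived internally).
  α₀ ≡ 0 in the baseline model.  α₀ is redrawn per replicate, treating the
  unknown cryptic-habitat map as uncertainty to be integrated over rather
  than a fixed landscape feature.

## Movement

* Local dispersal: each adult (all three adult classes; never juveniles or
  aestivators) leaves with probability d per day; the destination among
  neighbours within L_D is multinomial with weights ∝ (L_D − d_ij).
  Support is the open ball (weight 0 at d_ij = L_D; the tie is measure-zero
  but fixed for reproducibility).  Neighbour search uses a KD-tree on a
  local planar projection with an exact haversine refinement; results are
  identical to a brute-force scan (tested).  Emigrant class/age
  composition per destination is a multivariate-hypergeometric split, so
  dispersal conserves adults exactly.
* Long-distance migration: inside the NE→SW window (default 1 Nov–31 Dec,
  Harmattan) and the SW→NE window (1 Jun–31 Jul, monsoon onset) mated
  females initiate with probability d_M per day, die en route with
  probability μ_M, and otherwise relocate to a settlement drawn uniformly
  from the 90° wedge (±45° about the travel bearing, boundary excluded)
  extending to the region edge.  The wedge rule is the simplest geometry
  honouring "direction plus extent"; it is isolated behind
  `build_wedges()` so half-plane or corridor variants can be swapped in.
  Females with an empty wedge (corner sites) do not migrate.  Relocation
  is instantaneous (travel time ≪ the seasonal windows it would compete
  with).

## Aestivation

During (t_A1, t_A2) each mated female enters dormancy with probability ψ
per day; survival over the whole dormant period, 1 − μ_E, is drawn at
entry; survivors are booked to a uniform-random integer day of the
emergence window (t_A3, t_A4), always the next occurrence of that
day-of-year.  Only mated females aestivate or migrate (taken literally);
virgin females and males do neither.

## Distances and geography

Great-circle (haversine) distances on a spherical Earth, R = 6371 km; at a
regional extent projection error is negligible and no projection dependency
is needed.  Water input is GeoJSON (lines/polygons with a two-class
perennial attribute); rainfall is NetCDF (time, lat, lon) or a long-format
CSV; settlements are delimited text.  All loaders clip to the simulation
square, preserve class flags, and are round-trip tested against the
synthetic generator's writers.

## Parameter defaults

| symbol | meaning | default | provenance |
|---|---|---|---|
| μ_A | adult mortality /day | 0.125 | model description |
| β | males at p_m = 0.5 | 100 | model description |
| T_L | development time (days) | 12 | literature-scale placeholder |
| μ_J | juvenile density-independent mortality /day | 0.05 | placeholder |
| θ | eggs /mated female /day | 9 | placeholder |
| α₁ | rainfall-term asymptote (juveniles) | 2000 | calibration placeholder |
| α₂ | water-term asymptote (juveniles) | 4000 | calibration placeholder |
| φ | /mm | 0.05 | calibration placeholder |
| κ | /km | 0.3 | calibration placeholder |
| δ | /mm | 0.05 | calibration placeholder |
| L_w | water-search radius (km) | 2 | calibration placeholder |
| d | local dispersal /day | 0.01 | mid-range of field estimates |
| L_D | neighbourhood radius (km) | 15 | placeholder |
| ψ, μ_E | aestivation | 0 (off), 0.9 | scenario values |
| d_M, μ_M | migration | 0 (off), 0.99 | scenario values |
| t_A1..t_A4 | aestivation windows | 1 Oct–30 Nov, 1 Jun–21 Jul | regional seasonality |
| t_D1..t_D4 | migration windows | 1 Nov–31 Dec, 1 Jun–31 Jul | regional wind seasonality |

The original calibration constants for the carrying-capacity terms are not
published in the model's main description; the values above were chosen
once so that a well-watered settlement supports order-10³ adults and a
rain-free settlement supports none, and are clearly marked as placeholders
in `config.py`.  Anyone applying the model to real data should refit them
to local abundance estimates.

## Initialisation and outputs

The paperless questions of initialisation are resolved as: every
settlement is inoculated with 500 males + 500 mated females at the start of
a rainy season (1 June), followed by ≥ 2 burn-in years excluded from all
summaries — unsustainable populations die out, sustainable ones reach
quasi-equilibrium.  "Rainy-season occupancy" is ≥ 1 active adult (M+V+F;
dormant females excluded) on 19 October.  "Persistent" settlements are
classified by re-running with d = ψ = d_M = α₀ = 0 for 10 years and
requiring presence (any life stage) at every 365-day anniversary of the
start, majority-voted across replicates.  Replicate RNG streams are
spawned from the master seed (`numpy` PCG64 via `SeedSequence.spawn`), so
results are platform-independent and replicate-order invariant.

When a run outlives its rainfall series, the final 52 weeks are cycled;
the induced 1 day/year seasonal drift is irrelevant to the
presence/absence questions the long runs answer.

## Derived statistics

* Lifetime movement probability: the chance an adult ever changes
  settlement before death.  Movement and death compete daily, and a move
  made on the day of death counts — this matches how mark-recapture
  studies score a recaptured disperser — giving
  `d/(d + μ_A − d·μ_A)` (≈ 0.0386 for d = 0.005, μ_A = 0.125, i.e. ≈ 0.04),
  cross-checked by simulating individual lifetimes.  Note this convention
  differs slightly from the in-simulation event order, where that day's
  dispersal pool is the post-mortality population; the difference is a
  factor (1 − μ_A) on the per-day move probability.
* Resurgence date: first day of a simulation year (years start 1 June) on
  which a site's active-mated-female count reaches 10% of its in-year
  peak.  The threshold is a fraction of the site-year peak so the statistic
  is invariant to population scale; 10% is a repo definition chosen to sit
  above dry-season noise but early in the growth phase.
* Occupancy correlates: point-biserial correlation between
  colonised/unoccupied status and (i) distance to the nearest persistent
  settlement, (ii) number of settlements within 10 km, computed over
  non-persistent sites.  "Colonised" means occupied on the reference date
  in ≥ 50% of post-burn-in replicate-years.

## Synthetic landscapes

The generator emulates the statistical structure of the study region so
every analysis runs without external data:

* settlements from a Thomas cluster process (Poisson parents, Gaussian
  offspring), because the occupancy analyses depend on heterogeneous
  settlement density; an optional northern thinning factor makes Sahelian
  rows sparser;
* water courses as persistent-heading random walks laid until the declared
  km-per-100-km² density is reached exactly, with perennial courses
  optionally confined to a southern belt;
* weekly rainfall = seasonal Gaussian bump (centre ~mid-August) × linear
  north–south aridity gradient × region-wide lognormal year multiplier
  (mean 1), truncated to zero below 0.5 mm/week so arid dry seasons are
  genuinely rain-free.  Interannual multipliers are i.i.d. by default; an
  AR(1) switch exists for autocorrelated rainfall, off by default.

Three presets ship: `arid-north` (the main experimental scene: strong
gradient, perennial water only in the south, ≥ 6 rain-free months in the
north), `wet-south` (no zero-rain week in the southern rows) and
`sahel-remote` (sparse northern settlements > 30 km from perennial water).

What the synthetic scenes do *not* emulate: real drainage topology and
flow accumulation, spatially correlated rainfall anomalies, settlement
size/population attributes, and the empirical joint distribution of
settlements and rivers (villages cluster along real rivers).  Passing
tests on these landscapes therefore demonstrates correct mechanics and
qualitative behaviour (which processes can rescue which kinds of site),
not calibrated quantitative predictions for the real region — the
published full-data percentages additionally depend on the unavailable
calibration constants.

## Problem sizes in the shipped tests

The end-to-end checks use a 300 km, 200-settlement `arid-north` scene with
5 simulated years (2 burn-in) and 10 replicates per configuration, a
10-year isolation run for the persistence classification, 300 parallel
single-settlement replicates for the deterministic-limit comparison and
10⁶ simulated lifetimes for the dispersal conversion — sizes chosen to
keep the whole suite under ~10 minutes on one CPU while leaving
Monte-Carlo error well below the effect sizes being asserted.

## Known limitations

* No temperature/humidity dependence of vital rates; no egg/larva/pupa
  substages; no hydrological routing, pooling of drying streams, or
  rain-flushing of larval sites.
* Migration is a single-day relocation without wind-field trajectories or
  distance-dependent survival.
* The deterministic-limit oracle matches the stochastic mean only where
  fluctuations are small relative to α (Jensen-gap effects appear for
  small populations); the tests use α = 5000 accordingly.
* Default carrying-capacity constants are placeholders (above); absolute
  occupancy percentages on synthetic scenes should not be read as
  predictions for the real region.
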