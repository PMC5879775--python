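# sahelsim

Stochastic, spatially explicit simulation of *Anopheles gambiae* s.l.
metapopulation dynamics on networks of human settlements in West Africa.

In the Sahel, malaria vectors are found in villages every rainy season even
where all surface water vanishes for six months or more — yet an isolated
mosquito population cannot survive a rain-free dry season.  `sahelsim` is an
individual-based model built to weigh the candidate explanations against
each other: **local dispersal** from populations that persist next to
permanent water, **aestivation** (dry-season dormancy of mated females),
**long-distance wind-assisted migration**, and **small permanent larval
sites** (wells, containers and other cryptic year-round habitat).  It is
aimed at vector ecologists and modellers who want a transparent,
reproducible test bed for dry-season persistence hypotheses.

## Model core

Each settlement x holds integer counts of juveniles (ages 1..T_L days),
adult males M, virgin females V and mated females F, updated daily by
binomial/Poisson draws:

* juveniles survive each day with
  `p_s = [α(x,t) / (α(x,t) + J_T)]^(1/T_L) · (1 − μ_J)`
  where J_T is the settlement's juvenile total, so holding J_T = α over a
  full development kills exactly half the cohort from competition;
* emergers become male or virgin female with equal probability; virgins
  mate with probability `p_m = M / (β + M)`; mated females lay
  Poisson(θ) eggs per day; adults die with probability μ_A per day;
* the larval carrying-capacity scale follows weekly rainfall r(x,t) (mm)
  and the water courses within L_w km of the settlement,

  `α(x,t) = α₀(x) + α₁(1 − e^(−φ r)) + α₂(1 − e^(−κ[W_p + W_n(1 − e^(−δ r))]))`

  with W_p / W_n the km of perennial / intermittent courses and α₀(x) a
  lognormal per-settlement constant for cryptic permanent habitat (zero in
  the baseline model);
* adults disperse with probability d per day to settlements within L_D km,
  destination weights ∝ (L_D − d_ij); in seasonal windows mated females
  enter aestivation (probability ψ per day, surviving with 1 − μ_E) or
  initiate NE↔SW migration (probability d_M per day, surviving with
  1 − μ_M) to a uniform-random settlement in the 90° wedge of the region
  along the direction of travel.

Settlements, rivers/lakes and a 0.5° weekly rainfall grid can be loaded
from CSV / GeoJSON / NetCDF, or generated by the built-in synthetic
landscape module (Thomas-clustered settlements, random-walk river networks,
seasonal rainfall with a north–south aridity gradient) so that every
analysis runs without any external data.

## Worked example

```python
from dataclasses import replace
import sahelsim as ss
from sahelsim import analysis
from sahelsim.synthetic_landscape import generate_landscape, reference_scenarios
from sahelsim.engine import classify_persistent

spec = replace(reference_scenarios()["arid-north"], seed=5,
               n_settlements=80, side_km=200.0, n_years=4)
scape = generate_landscape(spec)
print(f"{scape.n_settlements} settlements, {len(scape.water)} water segments")

cfg = ss.SimulationConfig(years=4, burnin_years=2, replicates=3, seed=1)
persistent = classify_persistent(cfg, scape, years=6)
print(f"persistent in isolation: {persistent.sum()}/{len(persistent)}")

for d in (0.0, 0.01):
    run_cfg = ss.SimulationConfig(years=4, burnin_years=2, replicates=3, seed=1)
    run_cfg.movement.d = d
    result = ss.run_simulation(run_cfg, scape)
    unocc = 1.0 - ss.occupancy_on_date(result).mean()
    print(f"d={d}: unoccupied fraction on 19 Oct = {unocc:.3f}")

p = analysis.lifetime_movement_probability(0.005, 0.125)
print(f"lifetime movement probability at d=0.005: {p:.4f}")
```

prints

```
80 settlements, 65 water segments
persistent in isolation: 8/80
d=0.0: unoccupied fraction on 19 Oct = 0.900
d=0.01: unoccupied fraction on 19 Oct = 0.625
lifetime movement probability at d=0.005: 0.0386
```

Only 8 of 80 settlements — those beside perennial water or in the wetter
south — sustain a population with every rescue process switched off, and
90% of settlements are empty on the late-rainy-season reference date
(19 October).  Allowing realistic local dispersal (1% of adults moving per
day) lets the persistent "mainland" populations recolonise their
neighbourhoods each season, cutting the unoccupied fraction to 62.5%; the
remaining empty sites are the arid, isolated north, which in the model can
only be filled by aestivation, migration or permanent larval sites (see
`tests/test_acceptance.py` for those comparisons).  The last line converts
the daily dispersal probability d = 0.005 into the lifetime probability
that an adult ever changes settlement (≈ 0.04), the scale on which
mark-release-recapture field estimates are reported.

A thin CLI wraps the same functionality:

```sh
sahelsim generate-landscape --preset arid-north --seed 2 --out-dir land/
sahelsim simulate --config cfg.yaml --out results/
sahelsim classify-persistent --config cfg.yaml --out persistent.csv
sahelsim summarize --results results/ --out summary.csv
```

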