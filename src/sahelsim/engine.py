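"""Simulation orchestration: daily loop, replicates, RNG, persistence outputs.

The daily event order is fixed: (1) refresh alpha at week boundaries,
(2) juvenile survival/ageing, (3) emergence, (4) adult survival,
(5) mating, (6) aestivation entry and ledger release, (7) oviposition,
(8) movement (local dispersal, then long-distance migration).  Newly
emerged adults face mortality and can mate on their first day; movement
comes last so within-site demography stays local.

Time is day-indexed from the start date on a 365-day no-leap calendar.
Every settlement starts with a fixed adult inoculum at the beginning of a
rainy season, followed by burn-in years that are excluded from occupancy
summaries, so unsustainable populations die out and sustainable ones
equilibrate before anything is measured.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import demography as dem
from . import movement as mov
from .demography import AestivationParams, DemographyParams, PopulationState
from .geodata import Landscape
from .habitat import HabitatParams, HabitatTable, build_habitat, sample_small_permanent_sites
from .movement import MovementParams


@dataclass
class SimulationConfig:
    demography: DemographyParams = field(default_factory=DemographyParams)
    habitat: HabitatParams = field(default_factory=HabitatParams)
    movement: MovementParams = field(default_factory=MovementParams)
    aestivation: AestivationParams = field(default_factory=AestivationParams)
    years: int = 5               # total simulated years, burn-in included
    burnin_years: int = 2        # initial years excluded from summaries
    start_doy: int = 152         # simulation starts 1 June (rainy-season onset)
    init_males: int = 500        # adult inoculum per settlement at t = 0
    init_mated: int = 500
    replicates: int = 10
    seed: int = 0
    reference_doy: int = 292     # 19 October: late-rainy-season occupancy date
    validate: bool = False       # per-day conservation / integrity asserts

    def __post_init__(self) -> None:
        if self.years < 1 or self.burnin_years < 0 or self.burnin_years >= self.years:
            raise ValueError("need years >= 1 and 0 <= burnin_years < years")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 1 <= self.start_doy <= 365 or not 1 <= self.reference_doy <= 365:
            raise ValueError("start_doy/reference_doy must be day-of-year in 1..365")

    def hash(self) -> str:
        return hashlib.sha1(json.dumps(asdict(self), sort_keys=True, default=str)
                            .encode()).hexdigest()[:12]


@dataclass
class SimulationResult:
    """Per-settlement daily series plus the occupancy-relevant snapshots."""

    config: SimulationConfig
    n_sites: int
    n_days: int
    active: np.ndarray          # (reps, n_days, n_sites) M+V+F, int32
    mated: np.ndarray           # (reps, n_days, n_sites) F, int32
    year_end_total: np.ndarray  # (reps, years, n_sites) whole population incl. J and E
    extinct_at: list            # per replicate: day of metapopulation extinction or None
    metadata: dict

    @property
    def years(self) -> int:
        return self.config.years

    def day_index(self, doy: int, year: int) -> int:
        """Absolute day index of a day-of-year within simulation year ``year``."""
        return (doy - self.config.start_doy) % 365 + 365 * year

    def to_frame(self, replicate: int = 0):
        """Tidy daily series of one replicate (site, day, active, mated)."""
        import pandas as pd

        reps, days, sites = self.active.shape
        dd, ss = np.meshgrid(np.arange(days), np.arange(sites), indexing="ij")
        return pd.DataFrame({
            "day": dd.ravel(), "settlement": ss.ravel(),
            "active_adults": self.active[replicate].ravel(),
            "mated_females": self.mated[replicate].ravel(),
        })


def _effective_week(week: int, n_weeks: int) -> int:
    """Cycle the final 52 rainfall weeks when a run outlives its series."""
    if week < n_weeks:
        return week
    if n_weeks < 52:
        return week % n_weeks
    return n_weeks - 52 + (week - n_weeks) % 52


def _run_replicate(config: SimulationConfig, table: HabitatTable,
                   network, wedges, rng: np.random.Generator):
    dp, hp, mp, ap = (config.demography, config.habitat,
                      config.movement, config.aestivation)
    n = table.n_settlements
    n_days = config.years * 365
    state = PopulationState.seeded(n, dp.T_L, config.init_males,
                                   config.init_mated, dp.max_adult_age)
    active = np.zeros((n_days, n), np.int32)
    mated = np.zeros((n_days, n), np.int32)
    year_end = np.zeros((config.years, n), np.int64)
    extinct_at = None
    alpha = table.weekly_alpha(0, hp)
    for day in range(n_days):
        if day % 7 == 0:
            alpha = table.weekly_alpha(
                _effective_week(day // 7, table.rain.shape[0]), hp)
        doy = (config.start_doy - 1 + day) % 365 + 1

        emergers = dem.step_juveniles(state, alpha, dp, rng)
        males, females = dem.emerge(emergers, rng)
        state.M[:, 0] += males
        state.V[:, 0] += females
        ledger_before = int(state.aest_total.sum()) if config.validate else 0
        tally = dem.step_adults(state, dp, ap, doy, day, config.start_doy, rng)
        if config.validate:
            ledger_after = int(state.aest_total.sum())
            booked = tally["aest_entered"] - tally["aest_died_on_entry"]
            if ledger_after != ledger_before + booked - tally["aest_released"]:
                raise AssertionError(f"aestivation ledger not conserved on day {day}")
        dem.oviposit(state, dp, rng)

        before_move = int(state.active_adults.sum())
        if network is not None:
            mov.apply_local_dispersal(state, network, mp.d, rng)
        mig_deaths = 0
        if wedges is not None:
            mig_deaths = mov.apply_migration(state, wedges, mp, doy, rng)
        if config.validate:
            state.validate()
            after = int(state.active_adults.sum())
            if after != before_move - mig_deaths:
                raise AssertionError(
                    f"adult conservation violated on day {day}: "
                    f"{before_move} -> {after} with {mig_deaths} migration deaths")

        active[day] = state.active_adults
        mated[day] = state.F_total
        if (day + 1) % 365 == 0:
            year_end[(day + 1) // 365 - 1] = state.total_population
        if extinct_at is None and int(state.total_population.sum()) == 0:
            extinct_at = day
            break  # absorbing state: remaining records stay zero
    return active, mated, year_end, extinct_at


def run_simulation(config: SimulationConfig, landscape: Landscape) -> SimulationResult:
    """Run all replicates; reproducible given ``config.seed``.

    Replicate seeds are spawned deterministically from the master seed and
    the per-settlement small-permanent-site constants alpha0 are redrawn
    for each replicate.
    """
    base_table = build_habitat(landscape, config.habitat, rng=0)
    network = (mov.build_network(landscape, config.movement.L_D)
               if config.movement.d > 0 else None)
    wedges = (mov.build_wedges(landscape)
              if config.movement.d_M > 0 else None)
    streams = np.random.SeedSequence(config.seed).spawn(config.replicates)
    n_days = config.years * 365
    n = landscape.n_settlements
    active = np.zeros((config.replicates, n_days, n), np.int32)
    mated = np.zeros((config.replicates, n_days, n), np.int32)
    year_end = np.zeros((config.replicates, config.years, n), np.int64)
    extinct = []
    for rep, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        table = HabitatTable(base_table.W_p, base_table.W_n,
                             sample_small_permanent_sites(n, config.habitat, rng),
                             base_table.rain)
        a, m, ye, ext = _run_replicate(config, table, network, wedges, rng)
        active[rep], mated[rep], year_end[rep] = a, m, ye
        extinct.append(ext)
    meta = {"config_hash": config.hash(), "seed": config.seed,
            "n_settlements": n, "n_days": n_days}
    return SimulationResult(config, n, n_days, active, mated, year_end,
                            extinct, meta)


def occupancy_on_date(result: SimulationResult, doy: int | None = None,
                      include_burnin: bool = False) -> np.ndarray:
    """Occupancy flags (reps, years, sites): >= 1 *active* adult on ``doy``.

    Aestivating females do not count as occupancy.  Burn-in years are
    excluded unless requested.  A reference date outside the simulated
    range is fatal.
    """
    cfg = result.config
    doy = cfg.reference_doy if doy is None else doy
    if not 1 <= doy <= 365:
        raise ValueError("doy must be a day-of-year in 1..365")
    first_year = 0 if include_burnin else cfg.burnin_years
    days = [result.day_index(doy, y) for y in range(first_year, cfg.years)]
    if not days or max(days) >= result.n_days or min(days) < 0:
        raise ValueError("reference date outside the simulated range")
    return result.active[:, days, :] >= 1


def classify_persistent(config: SimulationConfig, landscape: Landscape,
                        years: int = 10, replicates: int | None = None) -> np.ndarray:
    """Persistent-population flags per settlement.

    Re-runs the model with local dispersal, aestivation, migration and
    small permanent sites all switched off for ``years`` years; a
    settlement is persistent if its population (all life stages) is present
    at every year-end, by majority vote across replicates.
    """
    cfg = copy.deepcopy(config)
    cfg.movement.d = 0.0
    cfg.movement.d_M = 0.0
    cfg.aestivation.psi = 0.0
    cfg.habitat.alpha0_mean = 0.0
    cfg.habitat.alpha0_var = 0.0
    cfg.years = years
    cfg.burnin_years = 0
    if replicates is not None:
        cfg.replicates = replicates
    result = run_simulation(cfg, landscape)
    present_all_years = (result.year_end_total >= 1).all(axis=1)  # (reps, sites)
    return present_all_years.mean(axis=0) > 0.5
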