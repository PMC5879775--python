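"""Daily stochastic demography of a local mosquito population.

Each settlement holds integer counts of juveniles (by age class, egg to
pre-reproductive adult over a fixed T_L days), adult males, virgin females
and mated females, plus a ledger of aestivating (dormant) mated females
keyed by their future emergence day.  Every count is updated daily by draws
from binomial/Poisson distributions:

* juveniles survive with p_s = [alpha/(alpha + J_T)]^(1/T_L) * (1 - mu_J)
  and age by one day; survivors completing age T_L emerge as adult males or
  virgin females with equal probability;
* adults die with probability mu_A per day; virgin females mate with
  probability p_m = M / (beta + M); mated females lay Poisson(theta) eggs
  per day;
* during an annual entry window mated females enter aestivation with daily
  probability psi, survive it with probability 1 - mu_E, and the survivors
  re-emerge on a uniform-random day of a later emergence window.

For efficiency all operations are vectorised over settlements: a
``PopulationState`` stores the whole metapopulation (a single isolated
settlement is simply ``n_sites=1``).  When a maximum adult age is set (the
30-day longevity-cap model variant), adults additionally carry an age
dimension and die on reaching the cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DemographyParams:
    """Life-history parameters.

    ``mu_A`` = 0.125/day and ``beta`` = 100 males follow the model's main
    description; T_L, mu_J and theta are literature-scale placeholders (the
    original calibration constants are not published in the main text).
    """

    T_L: int = 12             # days, egg-to-adult development (constant)
    mu_J: float = 0.05        # per-day density-independent juvenile mortality
    mu_A: float = 0.125       # per-day adult mortality probability
    theta: float = 9.0        # expected eggs per mated female per day
    beta: float = 100.0       # males at which daily mating probability is 0.5
    max_adult_age: int | None = None  # optional longevity cap (days)

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu_J <= 1.0 and 0.0 <= self.mu_A <= 1.0):
            raise ValueError("mu_J and mu_A must be probabilities")
        if self.T_L < 1 or int(self.T_L) != self.T_L:
            raise ValueError("T_L must be a positive integer")
        if self.theta < 0 or self.beta <= 0:
            raise ValueError("theta >= 0 and beta > 0 required")
        if self.max_adult_age is not None and self.max_adult_age < 1:
            raise ValueError("max_adult_age must be >= 1 day")


@dataclass
class AestivationParams:
    """Dry-season dormancy: entry window, survival, emergence window.

    Windows are day-of-year intervals (1..365, inclusive, no-leap calendar)
    and must not overlap.  Defaults put entry at the end of the rains
    (Oct-Nov) and emergence at the next onset (Jun-Jul).
    """

    psi: float = 0.0          # per-day entry probability (0 = no aestivation)
    mu_E: float = 0.9         # probability of dying over aestivation
    t_A1: int = 274           # entry window start (1 October)
    t_A2: int = 334           # entry window end (30 November)
    t_A3: int = 152           # emergence window start (1 June)
    t_A4: int = 202           # emergence window end (21 July)

    def __post_init__(self) -> None:
        if not (0.0 <= self.psi <= 1.0 and 0.0 <= self.mu_E <= 1.0):
            raise ValueError("psi and mu_E must be probabilities")
        for t in (self.t_A1, self.t_A2, self.t_A3, self.t_A4):
            if not 1 <= t <= 365:
                raise ValueError("window days must be day-of-year in 1..365")
        if self.t_A1 > self.t_A2 or self.t_A3 > self.t_A4:
            raise ValueError("windows must be ordered (start <= end)")
        entry = set(range(self.t_A1, self.t_A2 + 1))
        emerg = set(range(self.t_A3, self.t_A4 + 1))
        if entry & emerg:
            raise ValueError("entry and emergence windows overlap")


def in_window(day_of_year: int, start: int, end: int) -> bool:
    """Inclusive day-of-year window test (no wrap-around windows used)."""
    return start <= day_of_year <= end


class PopulationState:
    """Integer life-stage counts for ``n_sites`` settlements.

    ``J`` has shape (n_sites, T_L): column a holds juveniles of age a+1
    days.  Adult arrays have shape (n_sites, A) where A = 1 in the default
    model (no adult age structure) or ``max_adult_age`` in the capped
    variant, in which column a holds adults aged a days since emergence.
    ``aest`` maps absolute emergence day -> per-site counts of dormant
    mated females.
    """

    __slots__ = ("J", "M", "V", "F", "aest")

    def __init__(self, J, M, V, F, aest=None):
        self.J = np.asarray(J, dtype=np.int64)
        self.M = np.asarray(M, dtype=np.int64)
        self.V = np.asarray(V, dtype=np.int64)
        self.F = np.asarray(F, dtype=np.int64)
        self.aest = {} if aest is None else aest

    @classmethod
    def zeros(cls, n_sites: int, T_L: int, max_adult_age: int | None = None):
        A = max_adult_age or 1
        return cls(np.zeros((n_sites, T_L), np.int64),
                   np.zeros((n_sites, A), np.int64),
                   np.zeros((n_sites, A), np.int64),
                   np.zeros((n_sites, A), np.int64))

    @classmethod
    def seeded(cls, n_sites: int, T_L: int, males: int, mated: int,
               max_adult_age: int | None = None):
        """Inoculate every settlement with adults (age 0 where tracked)."""
        s = cls.zeros(n_sites, T_L, max_adult_age)
        s.M[:, 0] = males
        s.F[:, 0] = mated
        return s

    # -- totals -----------------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.J.shape[0]

    @property
    def J_T(self) -> np.ndarray:
        return self.J.sum(axis=1)

    @property
    def M_total(self) -> np.ndarray:
        return self.M.sum(axis=1)

    @property
    def V_total(self) -> np.ndarray:
        return self.V.sum(axis=1)

    @property
    def F_total(self) -> np.ndarray:
        return self.F.sum(axis=1)

    @property
    def active_adults(self) -> np.ndarray:
        """M + V + F per site; aestivating females are *not* active."""
        return self.M_total + self.V_total + self.F_total

    @property
    def aest_total(self) -> np.ndarray:
        if not self.aest:
            return np.zeros(self.n_sites, np.int64)
        return np.sum(list(self.aest.values()), axis=0)

    @property
    def total_population(self) -> np.ndarray:
        return self.J_T + self.active_adults + self.aest_total

    def validate(self) -> None:
        for name in ("J", "M", "V", "F"):
            arr = getattr(self, name)
            if np.any(arr < 0):
                raise AssertionError(f"negative count in {name}")
        for day, counts in self.aest.items():
            if np.any(counts < 0):
                raise AssertionError(f"negative aestivation count for day {day}")


# ---------------------------------------------------------------------------
# operations


def juvenile_survival_prob(alpha, J_T, p: DemographyParams):
    """Daily juvenile survival probability p_s (vectorised).

    The density-dependent factor is calibrated so that holding J_T = alpha
    over the whole development period kills exactly half the cohort; with
    alpha = 0 any competing juvenile dies.
    """
    alpha = np.asarray(alpha, dtype=float)
    J_T = np.asarray(J_T, dtype=float)
    denom = alpha + J_T
    ratio = np.divide(alpha, denom, out=np.ones_like(denom), where=denom > 0)
    return ratio ** (1.0 / p.T_L) * (1.0 - p.mu_J)


def step_juveniles(state: PopulationState, alpha, p: DemographyParams,
                   rng: np.random.Generator) -> np.ndarray:
    """Survive and age every juvenile class; return emergers per site.

    p_s is computed from the pre-update total J_T of each site and applied
    to every age class; survivors of the oldest class leave the juvenile
    pool as that day's emergers.
    """
    p_s = juvenile_survival_prob(alpha, state.J_T, p)
    survivors = rng.binomial(state.J, p_s[:, None])
    emergers = survivors[:, -1].copy()
    state.J[:, 1:] = survivors[:, :-1]
    state.J[:, 0] = 0
    return emergers


def emerge(emergers: np.ndarray, rng: np.random.Generator):
    """Split emergers into (males, virgin females) with equal probability."""
    males = rng.binomial(emergers, 0.5)
    return males, emergers - males


def mating_prob(M, beta: float):
    """Daily mating probability p_m = M / (beta + M)."""
    M = np.asarray(M, dtype=float)
    return M / (beta + M)


def release_aestivators(state: PopulationState, abs_day: int) -> np.ndarray:
    """Move ledger entries whose emergence day is ``abs_day`` back into F."""
    counts = state.aest.pop(abs_day, None)
    if counts is None:
        return np.zeros(state.n_sites, np.int64)
    state.F[:, 0] += counts
    return counts


def _book_aestivators(state: PopulationState, survivors: np.ndarray,
                      a: AestivationParams, abs_day: int, start_doy: int,
                      rng: np.random.Generator) -> None:
    """Assign surviving entrants a uniform emergence day in (t_A3, t_A4)."""
    if survivors.sum() == 0:
        return
    doy = (start_doy - 1 + abs_day) % 365 + 1
    window = np.arange(a.t_A3, a.t_A4 + 1)
    offsets = (window - doy) % 365
    offsets[offsets == 0] = 365
    split = rng.multinomial(survivors, np.full(len(window), 1.0 / len(window)))
    for k, off in enumerate(offsets):
        col = split[:, k]
        if col.any():
            target = abs_day + int(off)
            if target in state.aest:
                state.aest[target] += col
            else:
                state.aest[target] = col.astype(np.int64)


def step_adults(state: PopulationState, p: DemographyParams,
                a: AestivationParams, day_of_year: int, abs_day: int,
                start_doy: int, rng: np.random.Generator) -> dict:
    """One day of adult demography: death, mating, aestivation exit/entry.

    Returns a tally dict used by the engine's conservation accounting.
    Newly emerged adults must already have been added (they face mortality
    and can mate on their first day).  With an adult age structure the
    survivors also age one day and those reaching the cap are removed.
    """
    tally = {}
    before = int(state.active_adults.sum())
    state.M = rng.binomial(state.M, 1.0 - p.mu_A)
    state.V = rng.binomial(state.V, 1.0 - p.mu_A)
    state.F = rng.binomial(state.F, 1.0 - p.mu_A)
    if p.max_adult_age is not None and state.M.shape[1] > 1:
        for name in ("M", "V", "F"):
            arr = getattr(state, name)
            aged = np.zeros_like(arr)
            aged[:, 1:] = arr[:, :-1]      # the last column dies of old age
            setattr(state, name, aged)
    tally["adult_deaths"] = before - int(state.active_adults.sum())

    p_m = mating_prob(state.M_total, p.beta)
    matings = rng.binomial(state.V, p_m[:, None])
    state.V -= matings
    state.F += matings

    tally["aest_released"] = int(release_aestivators(state, abs_day).sum())

    entered = died = 0
    if a.psi > 0.0 and in_window(day_of_year, a.t_A1, a.t_A2):
        entrants = rng.binomial(state.F, a.psi)
        state.F -= entrants
        per_site = entrants.sum(axis=1)
        survivors = rng.binomial(per_site, 1.0 - a.mu_E)
        entered = int(per_site.sum())
        died = entered - int(survivors.sum())
        _book_aestivators(state, survivors, a, abs_day, start_doy, rng)
    tally["aest_entered"] = entered
    tally["aest_died_on_entry"] = died
    return tally


def oviposit(state: PopulationState, p: DemographyParams,
             rng: np.random.Generator) -> np.ndarray:
    """Each mated female lays Poisson(theta) eggs; eggs enter age class 1."""
    eggs = rng.poisson(p.theta * state.F_total)
    state.J[:, 0] += eggs
    return eggs
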