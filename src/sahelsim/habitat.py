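"""Larval carrying-capacity scale alpha(x, t) per settlement and week.

alpha(x, t) is the juvenile count at which density-dependent mortality over
the whole development period is 50%.  It is the sum of three terms:

    alpha(x,t) = alpha0(x)
               + alpha1 * (1 - exp(-phi * r(x,t)))
               + alpha2 * (1 - exp(-kappa * [W_p(x) + W_n(x) * (1 - exp(-delta * r(x,t)))]))

where r(x,t) is the weekly rainfall total (mm) of the settlement's grid
cell, W_p / W_n are the km of perennial / non-perennial water courses within
a radius L_w of the settlement, and alpha0(x) is an optional per-settlement
constant describing small permanent larval sites (wells, containers), drawn
lognormally across settlements and absent (zero) in the baseline model.
Rainfall recharges intermittent courses at rate delta, so under heavy rain
they supply the same habitat density as perennial ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geodata import Landscape, water_length_within


@dataclass
class HabitatParams:
    """Carrying-capacity coefficients (juvenile counts and per-unit rates)."""

    alpha1: float = 2000.0    # rainfall-term asymptote (juveniles)
    alpha2: float = 4000.0    # water-course-term asymptote (juveniles)
    phi: float = 0.05         # per-mm rainfall saturation rate
    kappa: float = 0.3        # per-km water-density saturation rate
    delta: float = 0.05       # per-mm replenishment rate of intermittent courses
    L_w: float = 2.0          # km water-search radius around a settlement
    alpha0_mean: float = 0.0  # small-permanent-site mean (juveniles); 0 = absent
    alpha0_var: float = 0.0   # small-permanent-site variance (juveniles^2)

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "phi", "kappa", "delta", "L_w",
                     "alpha0_mean", "alpha0_var"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.alpha0_var > 0 and self.alpha0_mean == 0:
            raise ValueError("alpha0_var > 0 with alpha0_mean = 0: lognormal undefined")


@dataclass
class SettlementHabitat:
    """The static habitat attributes of one settlement."""

    W_p: float = 0.0     # km perennial water within L_w
    W_n: float = 0.0     # km non-perennial water within L_w
    alpha0: float = 0.0  # small-permanent-site constant (juveniles)

    def __post_init__(self) -> None:
        if min(self.W_p, self.W_n, self.alpha0) < 0:
            raise ValueError("habitat attributes must be >= 0")


def compute_alpha(h: SettlementHabitat, p: HabitatParams, r):
    """Evaluate alpha(x, t) for weekly rainfall ``r`` (mm, scalar or array)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("rainfall must be >= 0")
    return alpha_values(np.asarray(h.W_p), np.asarray(h.W_n),
                        np.asarray(h.alpha0), p, r)


def alpha_values(W_p, W_n, alpha0, p: HabitatParams, r):
    """Vectorised alpha(x, t); broadcasts over settlements and weeks."""
    wet = W_p + W_n * (-np.expm1(-p.delta * r))
    return (alpha0
            + p.alpha1 * (-np.expm1(-p.phi * r))
            + p.alpha2 * (-np.expm1(-p.kappa * wet)))


def sample_small_permanent_sites(n: int, p: HabitatParams,
                                 rng: np.random.Generator) -> np.ndarray:
    """Draw per-settlement alpha0 values.

    alpha0 is lognormal across settlements with *natural-scale* mean
    ``alpha0_mean`` and variance ``alpha0_var`` (the conventional log-scale
    parameters are derived internally).  A zero mean means the sites are
    absent everywhere; zero variance gives a constant.
    """
    m, v = p.alpha0_mean, p.alpha0_var
    if m == 0.0:
        return np.zeros(n)
    if v == 0.0:
        return np.full(n, m)
    sigma2 = np.log1p(v / m ** 2)
    mu = np.log(m) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)


@dataclass
class HabitatTable:
    """Per-settlement habitat attributes plus the bound rainfall series."""

    W_p: np.ndarray          # (n,) km
    W_n: np.ndarray          # (n,) km
    alpha0: np.ndarray       # (n,) juveniles
    rain: np.ndarray         # (n_weeks, n) mm/week per settlement

    @property
    def n_settlements(self) -> int:
        return len(self.W_p)

    def row(self, i: int) -> SettlementHabitat:
        return SettlementHabitat(float(self.W_p[i]), float(self.W_n[i]),
                                 float(self.alpha0[i]))

    def weekly_alpha(self, week: int, p: HabitatParams) -> np.ndarray:
        """alpha vector for one rainfall week (clamped to the last week)."""
        w = min(week, self.rain.shape[0] - 1)
        return alpha_values(self.W_p, self.W_n, self.alpha0, p, self.rain[w])


def build_habitat(landscape: Landscape, p: HabitatParams,
                  rng: np.random.Generator | int | None = None) -> HabitatTable:
    """Measure W_p/W_n around every settlement, draw alpha0, bind rainfall."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    lon, lat = landscape.coords
    n = landscape.n_settlements
    W_p = np.zeros(n)
    W_n = np.zeros(n)
    for i in range(n):
        W_p[i], W_n[i] = water_length_within(lon[i], lat[i], landscape.water, p.L_w)
    alpha0 = sample_small_permanent_sites(n, p, rng)
    return HabitatTable(W_p, W_n, alpha0, landscape.settlement_rain_series())
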