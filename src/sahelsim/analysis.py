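"""Summary analyses of simulation output.

Implements the model's comparative statistics: unoccupied-fraction curves
over parameter sweeps, the island-mainland correlates (distance to the
nearest persistent population vs local settlement density), the seasonal
local-dynamics signatures that distinguish the dry-season hypotheses, and
the conversion between the daily dispersal probability and the lifetime
probability of an inter-settlement move.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .engine import SimulationResult, occupancy_on_date
from .geodata import Landscape, distance_km


def unoccupied_fraction_curve(results: dict) -> pd.DataFrame:
    """Unoccupied fraction on the reference date per swept parameter value.

    ``results`` maps a parameter value (e.g. a dispersal rate d) to a
    SimulationResult on the *same* landscape.  Returns a tidy frame with
    the mean and SD across replicates of the fraction of settlements
    without an active adult, per post-burn-in year.
    """
    n_sites = {r.n_sites for r in results.values()}
    if len(n_sites) > 1:
        raise ValueError("results come from different landscapes")
    rows = []
    for value, result in results.items():
        occ = occupancy_on_date(result)  # (reps, years, sites)
        unocc = 1.0 - occ.mean(axis=2)   # (reps, years)
        for y in range(unocc.shape[1]):
            rows.append({
                "param": value,
                "year": result.config.burnin_years + y,
                "mean_unoccupied": float(unocc[:, y].mean()),
                "sd_unoccupied": float(unocc[:, y].std(ddof=1)) if unocc.shape[0] > 1 else 0.0,
                "n_unoccupied": float((1.0 - occ.mean(axis=2)).mean() * result.n_sites),
            })
    return pd.DataFrame(rows)


@dataclass
class SiteCorrelates:
    """Per-settlement occupancy correlates and the two headline correlations."""

    table: pd.DataFrame           # id, class, dist_to_persistent_km, density_10km, occupancy
    corr_distance: float          # point-biserial corr(occupied, distance), non-persistent sites
    corr_density: float           # point-biserial corr(occupied, density)


def site_correlates(result: SimulationResult, persistent: np.ndarray,
                    landscape: Landscape, density_radius_km: float = 10.0,
                    colonised_threshold: float = 0.5) -> SiteCorrelates:
    """Distance-to-persistent and settlement-density correlates of occupancy.

    Sites are classed persistent / colonised / unoccupied, where "colonised"
    means occupied on the reference date in at least ``colonised_threshold``
    of post-burn-in replicate-years.  The two point-biserial correlations
    are computed over non-persistent sites only (persistent sites have
    distance 0 by definition and would tautologically inflate the contrast).
    """
    lon, lat = landscape.coords
    n = landscape.n_settlements
    persistent = np.asarray(persistent, dtype=bool)
    dist = np.zeros(n)
    if persistent.any():
        plon, plat = lon[persistent], lat[persistent]
        for i in range(n):
            dist[i] = 0.0 if persistent[i] else distance_km(lon[i], lat[i], plon, plat).min()
    else:
        dist[:] = np.inf
    density = np.array([
        int(np.sum(distance_km(lon[i], lat[i], lon, lat) <= density_radius_km)) - 1
        for i in range(n)])
    occ = occupancy_on_date(result).mean(axis=(0, 1))  # fraction of replicate-years
    cls = np.where(persistent, "persistent",
                   np.where(occ >= colonised_threshold, "colonised", "unoccupied"))
    table = pd.DataFrame({"id": landscape.settlements["id"], "class": cls,
                          "dist_to_persistent_km": dist,
                          "density_10km": density, "occupancy": occ})
    free = ~persistent
    occupied = (cls == "colonised")[free].astype(float)
    r_dist = r_dens = np.nan
    if 0 < occupied.sum() < occupied.size:
        r_dist = stats.pointbiserialr(occupied, dist[free]).statistic
        r_dens = stats.pointbiserialr(occupied, density[free]).statistic
    return SiteCorrelates(table, float(r_dist), float(r_dens))


def lifetime_movement_probability(d: float, mu_A: float,
                                  method: str = "closed_form",
                                  n_lifetimes: int = 1_000_000,
                                  rng: np.random.Generator | int | None = None) -> float:
    """Probability an adult ever moves between settlements before dying.

    Movement and death compete as daily events, with the day's dispersal
    counted even when the mosquito dies that same day (this is how
    mark-release-recapture studies count a move).  Closed form:
    d / (d + mu_A - d * mu_A).  The Monte-Carlo route simulates individual
    lifetimes: the first dispersal day is geometric in d, the death day
    geometric in mu_A, and a move happens iff it comes no later than death.
    """
    if not (0.0 <= d <= 1.0 and 0.0 <= mu_A <= 1.0):
        raise ValueError("d and mu_A must be probabilities")
    if d == 0.0:
        return 0.0
    if method == "closed_form":
        return d / (d + mu_A - d * mu_A) if (d + mu_A) > 0 else 0.0
    if method != "monte_carlo":
        raise ValueError(f"unknown method {method!r}")
    if mu_A == 0.0:
        return 1.0
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    move_day = rng.geometric(d, size=n_lifetimes)
    death_day = rng.geometric(mu_A, size=n_lifetimes)
    return float(np.mean(move_day <= death_day))


def local_dynamics_profiles(results: dict, landscape: Landscape,
                            persistent: np.ndarray, remote_km: float = 20.0,
                            threshold_frac: float = 0.1) -> pd.DataFrame:
    """Seasonal signatures of the dry-season hypotheses at remote sites.

    For each hypothesis (key of ``results``), each site farther than
    ``remote_km`` from a persistent population, each replicate and each
    post-burn-in year, extracts the active-mated-female series over the
    365-day year (years start at the rainy-season onset) and computes:

    * ``resurgence_day`` — first day the series reaches ``threshold_frac``
      of its in-year peak (scale-free by construction); NaN if the site
      stays empty all year;
    * ``dry_min`` — the in-year minimum of active mated females.

    Aestivation-maintained populations resurge early and synchronously,
    migration-maintained ones later and with more between-replicate
    spread, and permanent-site populations show a nonzero dry-season floor.
    """
    lon, lat = landscape.coords
    persistent = np.asarray(persistent, dtype=bool)
    if persistent.any():
        plon, plat = lon[persistent], lat[persistent]
        dist = np.array([distance_km(lon[i], lat[i], plon, plat).min()
                         for i in range(len(lon))])
    else:
        dist = np.full(len(lon), np.inf)
    remote = np.nonzero(~persistent & (dist > remote_km))[0]
    rows = []
    for name, result in results.items():
        cfg = result.config
        for rep in range(result.mated.shape[0]):
            for year in range(cfg.burnin_years, cfg.years):
                sl = slice(365 * year, 365 * (year + 1))
                series = result.mated[rep, sl, :]  # (365, n_sites)
                for site in remote:
                    f = series[:, site]
                    peak = int(f.max())
                    if peak == 0:
                        res_day = np.nan
                    else:
                        res_day = int(np.argmax(f >= threshold_frac * peak))
                    rows.append({"hypothesis": name, "site": int(site),
                                 "replicate": rep, "year": year,
                                 "resurgence_day": res_day,
                                 "dry_min": int(f.min()),
                                 "peak": peak})
    return pd.DataFrame(rows)


def resurgence_summary(profiles: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD of resurgence timing and dry-season floor per hypothesis."""
    g = profiles.groupby("hypothesis")
    return pd.DataFrame({
        "mean_resurgence_day": g["resurgence_day"].mean(),
        "sd_resurgence_day": g["resurgence_day"].std(),
        "mean_dry_min": g["dry_min"].mean(),
        "frac_site_years_active": g.apply(
            lambda t: float(np.mean(t["peak"] > 0)), include_groups=False),
    })
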