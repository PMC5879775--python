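"""Adult movement: local dispersal on the settlement network and seasonal
wind-aligned long-distance migration.

Local dispersal: every adult (male, virgin, mated — never juveniles or
aestivators) leaves its settlement with probability ``d`` per day and moves
to a neighbouring settlement within radius ``L_D``, chosen with probability
proportional to (L_D - d_ij).  Dispersal therefore conserves adults exactly;
the mean dispersal distance is shorter from densely surrounded settlements
than from isolated ones.

Long-distance migration: during an annual NE->SW window (and a mirrored
SW->NE window) each mated female initiates migration with probability
``d_M`` per day, dies en route with probability ``mu_M``, and otherwise
relocates to a settlement drawn uniformly from the 90-degree wedge of the
region extending from her settlement in the direction of travel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .demography import PopulationState, in_window
from .geodata import Landscape, distance_km


@dataclass
class MovementParams:
    d: float = 0.01        # per-day local dispersal probability per adult
    L_D: float = 15.0      # km neighbourhood radius
    d_M: float = 0.0       # per-day migration initiation probability (mated females)
    mu_M: float = 0.99     # probability of dying during migration
    t_D1: int = 305        # NE->SW window start (Harmattan onset, 1 November)
    t_D2: int = 365        # NE->SW window end (31 December)
    t_D3: int = 152        # SW->NE window start (monsoon onset, 1 June)
    t_D4: int = 212        # SW->NE window end (31 July)

    def __post_init__(self) -> None:
        for name in ("d", "d_M", "mu_M"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.L_D <= 0:
            raise ValueError("L_D must be > 0")
        if self.t_D1 > self.t_D2 or self.t_D3 > self.t_D4:
            raise ValueError("migration windows must be ordered")
        if set(range(self.t_D1, self.t_D2 + 1)) & set(range(self.t_D3, self.t_D4 + 1)):
            raise ValueError("migration windows overlap")


@dataclass
class DispersalNetwork:
    """Per-settlement neighbour sets with normalised (L_D - d_ij) weights."""

    neighbours: list   # [i] -> int array of neighbour ids (d_ij < L_D, j != i)
    distances: list    # [i] -> km to each neighbour
    weights: list      # [i] -> kernel weights, sum to 1 where non-empty
    L_D: float

    @property
    def n_sites(self) -> int:
        return len(self.neighbours)


@dataclass
class MigrationWedges:
    """Candidate destination sets per settlement for the two directions."""

    ne_sw: list  # [i] -> destinations lying to the south-west of i
    sw_ne: list  # [i] -> destinations lying to the north-east of i

    def __post_init__(self) -> None:
        # uniform destination weights, cached for the daily update
        self._w = {id(self.ne_sw): [np.full(len(w), 1.0 / len(w)) if len(w) else np.empty(0)
                                    for w in self.ne_sw],
                   id(self.sw_ne): [np.full(len(w), 1.0 / len(w)) if len(w) else np.empty(0)
                                    for w in self.sw_ne]}


def build_network(landscape: Landscape, L_D: float) -> DispersalNetwork:
    """Neighbours within the *open* ball of radius L_D, via a KD-tree on a
    local planar projection with an exact haversine refinement."""
    if L_D <= 0:
        raise ValueError("L_D must be > 0")
    lon, lat = landscape.coords
    x, y = landscape.bounds.to_local_km(lon, lat)
    tree = cKDTree(np.column_stack([x, y]))
    # planar distortion over a regional square is well under 2%
    candidates = tree.query_ball_tree(tree, r=L_D * 1.05)
    neighbours, distances, weights = [], [], []
    for i, cand in enumerate(candidates):
        js = np.array([j for j in cand if j != i], dtype=int)
        if len(js) == 0:
            neighbours.append(js)
            distances.append(np.empty(0))
            weights.append(np.empty(0))
            continue
        d_ij = distance_km(lon[i], lat[i], lon[js], lat[js])
        keep = d_ij < L_D
        js, d_ij = js[keep], d_ij[keep]
        w = L_D - d_ij
        neighbours.append(js)
        distances.append(d_ij)
        weights.append(w / w.sum() if len(w) else w)
    return DispersalNetwork(neighbours, distances, weights, L_D)


def _scatter(state_cols: np.ndarray, emig: np.ndarray, dests: list,
             dest_weights: list, rng: np.random.Generator) -> np.ndarray:
    """Allocate per-site emigrant vectors (over classes/ages) to destinations.

    ``emig`` is (n_sites, n_cols); ``dests[i]``/``dest_weights[i]`` give the
    candidate destinations of site i.  Destination totals are multinomial in
    the weights; the class/age composition of each destination's share is a
    multivariate-hypergeometric split of the emigrant vector, so totals are
    conserved exactly.  Returns the (n_sites, n_cols) arrival array.
    """
    arrivals = np.zeros_like(emig)
    totals = emig.sum(axis=1)
    for i in np.nonzero(totals > 0)[0]:
        per_dest = rng.multinomial(totals[i], dest_weights[i])
        remaining = emig[i].copy()
        for j, cnt in zip(dests[i], per_dest):
            if cnt == 0:
                continue
            take = rng.multivariate_hypergeometric(remaining, int(cnt))
            arrivals[j] += take
            remaining -= take
    return arrivals


def apply_local_dispersal(state: PopulationState, network: DispersalNetwork,
                          d: float, rng: np.random.Generator) -> int:
    """One day of local dispersal; returns the number of movers (conserved)."""
    if d <= 0.0:
        return 0
    A = state.M.shape[1]
    cols = np.concatenate([state.M, state.V, state.F], axis=1)
    emig = np.zeros_like(cols)
    movable = np.array([len(n) > 0 for n in network.neighbours])
    if movable.any():
        emig[movable] = rng.binomial(cols[movable], d)
    arrivals = _scatter(cols, emig, network.neighbours, network.weights, rng)
    cols = cols - emig + arrivals
    state.M, state.V, state.F = cols[:, :A], cols[:, A:2 * A], cols[:, 2 * A:]
    return int(emig.sum())


def build_wedges(landscape: Landscape, half_angle_deg: float = 45.0) -> MigrationWedges:
    """Destination sets: bearings within +/-45 degrees of SW (225) or NE (45).

    The wedge extends to the edge of the simulation square; a settlement is
    never its own destination.  Boundary bearings (exactly 45 degrees off
    the axis, e.g. due north for the NE wedge) are excluded, so the four
    cardinal directions belong to no wedge.
    """
    lon, lat = landscape.coords
    if len(lon) < 2:
        raise ValueError("need at least 2 settlements to build wedges")
    x, y = landscape.bounds.to_local_km(lon, lat)
    ne_sw, sw_ne = [], []
    for i in range(len(x)):
        dx = x - x[i]
        dy = y - y[i]
        bearing = np.degrees(np.arctan2(dx, dy)) % 360.0  # 0 = N, 90 = E
        off_sw = np.abs((bearing - 225.0 + 180.0) % 360.0 - 180.0)
        off_ne = np.abs((bearing - 45.0 + 180.0) % 360.0 - 180.0)
        self_mask = np.arange(len(x)) != i
        ne_sw.append(np.nonzero(self_mask & (off_sw < half_angle_deg))[0])
        sw_ne.append(np.nonzero(self_mask & (off_ne < half_angle_deg))[0])
    return MigrationWedges(ne_sw, sw_ne)


def apply_migration(state: PopulationState, wedges: MigrationWedges,
                    mp: MovementParams, day_of_year: int,
                    rng: np.random.Generator) -> int:
    """One day of long-distance migration; returns en-route deaths.

    Active only inside a migration window.  Mated females whose wedge set
    is empty (settlements at the corner of the region) do not migrate.
    """
    if mp.d_M <= 0.0:
        return 0
    if in_window(day_of_year, mp.t_D1, mp.t_D2):
        dests = wedges.ne_sw
    elif in_window(day_of_year, mp.t_D3, mp.t_D4):
        dests = wedges.sw_ne
    else:
        return 0
    movable = np.array([len(w) > 0 for w in dests])
    init = np.zeros_like(state.F)
    if movable.any():
        init[movable] = rng.binomial(state.F[movable], mp.d_M)
    per_site = init.sum(axis=1)
    deaths = 0
    survivors = np.zeros_like(init)
    for i in np.nonzero(per_site > 0)[0]:
        n_surv = rng.binomial(int(per_site[i]), 1.0 - mp.mu_M)
        deaths += int(per_site[i]) - int(n_surv)
        if n_surv:
            survivors[i] = rng.multivariate_hypergeometric(init[i], int(n_surv))
    arrivals = _scatter(state.F, survivors, dests, wedges._w[id(dests)], rng)
    state.F = state.F - init + arrivals
    return deaths
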