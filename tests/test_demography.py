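"""Tests of the daily stochastic demographic update."""

import numpy as np
import pytest

from sahelsim.demography import (AestivationParams, DemographyParams,
                                 PopulationState, emerge, juvenile_survival_prob,
                                 mating_prob, oviposit, release_aestivators,
                                 step_adults, step_juveniles)


def _state(n=1, T_L=12, J=None, M=0, V=0, F=0, max_age=None):
    s = PopulationState.zeros(n, T_L, max_age)
    if J is not None:
        s.J[:] = J
    s.M[:, 0] = M
    s.V[:, 0] = V
    s.F[:, 0] = F
    return s


# ------------------------------------------------------------- survival prob

def test_density_dependent_death_is_half_at_alpha():
    p = DemographyParams(T_L=10, mu_J=0.0)
    p_s = juvenile_survival_prob(500.0, 500.0, p)
    assert p_s == pytest.approx(0.5 ** 0.1, rel=1e-12)
    # cumulative density-dependent death over development is exactly 0.5
    assert 1.0 - p_s ** p.T_L == pytest.approx(0.5, rel=1e-12)


def test_survival_prob_edge_cases():
    p = DemographyParams(T_L=12, mu_J=0.0)
    assert juvenile_survival_prob(100.0, 0.0, p) == 1.0
    assert juvenile_survival_prob(0.0, 50.0, p) == 0.0
    assert juvenile_survival_prob(100.0, 30.0, DemographyParams(mu_J=1.0)) == 0.0


# ------------------------------------------------------------- juvenile step

def test_step_juveniles_all_die_when_alpha_zero(rng):
    s = _state(J=100)
    emergers = step_juveniles(s, np.array([0.0]), DemographyParams(), rng)
    assert emergers[0] == 0
    assert s.J_T[0] == 0


def test_step_juveniles_ages_and_emerges(rng):
    p = DemographyParams(T_L=3, mu_J=0.0)
    s = PopulationState.zeros(1, 3)
    s.J[0] = [10, 20, 30]
    # enormous alpha -> survival indistinguishable from certain
    emergers = step_juveniles(s, np.array([1e15]), p, rng)
    assert emergers[0] == 30
    np.testing.assert_array_equal(s.J[0], [0, 10, 20])


def test_step_juveniles_binomial_rate(rng):
    p = DemographyParams(T_L=10, mu_J=0.0)
    n0 = 100_000
    s = _state(T_L=10, J=0)
    s.J[0, 0] = n0
    alpha = np.array([float(n0)])  # J_T = alpha -> p_s = 0.5^{1/10}
    p_s = 0.5 ** 0.1
    step_juveniles(s, alpha, p, rng)
    sd = np.sqrt(n0 * p_s * (1 - p_s))
    assert abs(s.J[0, 1] - n0 * p_s) < 3 * sd


# ------------------------------------------------------------- emergence

def test_emerge_conserves_and_splits_evenly(rng):
    m, f = emerge(np.array([0]), rng)
    assert m[0] == 0 and f[0] == 0
    n = 1_000_000
    m, f = emerge(np.array([n]), rng)
    assert m[0] + f[0] == n
    assert abs(m[0] / n - 0.5) < 0.0015  # 3 binomial SDs


# ------------------------------------------------------------- mating

@pytest.mark.parametrize("M,beta,expected", [
    (100, 100.0, 0.5),   # M = beta -> one half
    (0, 100.0, 0.0),
    (300, 100.0, 0.75),
])
def test_mating_probability(M, beta, expected):
    assert mating_prob(M, beta) == pytest.approx(expected, rel=1e-12)


# ------------------------------------------------------------- adult step

def test_total_mortality_removes_all_active_adults(rng):
    s = _state(M=50, V=20, F=30)
    step_adults(s, DemographyParams(mu_A=1.0), AestivationParams(),
                day_of_year=10, abs_day=9, start_doy=1, rng=rng)
    assert s.active_adults[0] == 0


def test_no_aestivation_without_propensity(rng):
    s = _state(F=1000)
    step_adults(s, DemographyParams(), AestivationParams(psi=0.0),
                day_of_year=300, abs_day=100, start_doy=1, rng=rng)
    assert s.aest == {}


def test_aestivation_entry_chain_rate(rng):
    # F mated females, one entry day: ledger total ~ F*(1-mu_A)*psi*(1-mu_E)
    F, psi, mu_E, mu_A = 100_000, 0.01, 0.9, 0.125
    a = AestivationParams(psi=psi, mu_E=mu_E, t_A1=280, t_A2=280)
    s = _state(F=F)
    tally = step_adults(s, DemographyParams(mu_A=mu_A), a,
                        day_of_year=280, abs_day=0, start_doy=280, rng=rng)
    total = int(s.aest_total[0])
    expect = F * (1 - mu_A) * psi * (1 - mu_E)
    sd = np.sqrt(F * (1 - mu_A) * psi)  # dominated by the entry binomial
    assert abs(total - expect) < 3 * sd
    assert tally["aest_entered"] - tally["aest_died_on_entry"] == total


def test_aestivation_emergence_day_within_window(rng):
    a = AestivationParams(psi=0.5, mu_E=0.0, t_A1=274, t_A2=334,
                          t_A3=152, t_A4=202)
    s = _state(F=10_000)
    step_adults(s, DemographyParams(mu_A=0.0), a, day_of_year=280,
                abs_day=0, start_doy=280, rng=rng)
    # abs emergence days must correspond to day-of-year inside (t_A3, t_A4)
    for day in s.aest:
        doy = (280 - 1 + day) % 365 + 1
        assert 152 <= doy <= 202


def test_release_aestivators_conservation(rng):
    s = _state(F=0)
    assert release_aestivators(s, 5).sum() == 0  # empty ledger no-op
    s.aest[160] = np.array([5])
    release_aestivators(s, 160)
    assert s.F_total[0] == 5 and s.aest == {}

    # over a full cycle, released totals equal the surviving entries
    a = AestivationParams(psi=0.05, mu_E=0.5, t_A1=10, t_A2=40, t_A3=200, t_A4=250)
    s = _state(F=50_000)
    dp = DemographyParams(mu_A=0.0, theta=0.0)
    entered = died = 0
    for day in range(365):
        doy = day + 1
        t = step_adults(s, dp, a, doy, day, 1, rng)
        entered += t["aest_entered"]
        died += t["aest_died_on_entry"]
    assert entered > 0
    assert s.aest == {}  # every booked female released within the year
    assert s.F_total[0] == 50_000 - died


def test_overlapping_windows_rejected():
    with pytest.raises(ValueError, match="overlap"):
        AestivationParams(psi=0.1, t_A1=100, t_A2=200, t_A3=150, t_A4=250)


# ------------------------------------------------------------- oviposition

def test_oviposit_zero_cases(rng):
    s = _state(F=0)
    assert oviposit(s, DemographyParams(theta=9.0), rng)[0] == 0
    s = _state(F=100)
    assert oviposit(s, DemographyParams(theta=0.0), rng)[0] == 0


def test_oviposit_poisson_moments():
    rng = np.random.default_rng(7)
    F, theta = 10_000, 9.0
    draws = []
    for _ in range(200):
        s = _state(F=F)
        draws.append(oviposit(s, DemographyParams(theta=theta), rng)[0])
    draws = np.asarray(draws, dtype=float)
    mean = F * theta
    assert abs(draws.mean() - mean) < 3 * np.sqrt(mean / 200)
    assert draws.var() == pytest.approx(mean, rel=0.3)  # Poisson: var ~ mean


# ------------------------------------------------------------- cap variant

def test_adult_age_cap_removes_old_adults(rng):
    p = DemographyParams(mu_A=0.0, theta=0.0, max_adult_age=5)
    s = _state(M=100, V=0, F=0, max_age=5)
    a = AestivationParams()
    for day in range(4):
        step_adults(s, p, a, day + 1, day, 1, rng)
        assert s.M_total[0] == 100
    step_adults(s, p, a, 5, 4, 1, rng)
    assert s.M_total[0] == 0  # everyone hit the cap on day 5


# ------------------------------------------------------------- invariants

def test_counts_stay_nonnegative_under_random_updates():
    rng = np.random.default_rng(123)
    p = DemographyParams(T_L=5)
    a = AestivationParams(psi=0.2, t_A1=1, t_A2=100, t_A3=200, t_A4=260)
    s = _state(n=4, T_L=5, J=20, M=30, V=10, F=25)
    for day in range(300):
        alpha = rng.uniform(0, 200, size=4)
        step_juveniles(s, alpha, p, rng)
        males, females = emerge(rng.poisson(5, size=4), rng)
        s.M[:, 0] += males
        s.V[:, 0] += females
        step_adults(s, p, a, day % 365 + 1, day, 1, rng)
        oviposit(s, p, rng)
        s.validate()


def test_zero_population_is_absorbing():
    rng = np.random.default_rng(9)
    p = DemographyParams()
    a = AestivationParams(psi=0.1)
    s = PopulationState.zeros(3, p.T_L)
    for day in range(400):
        step_juveniles(s, np.full(3, 100.0), p, rng)
        step_adults(s, p, a, day % 365 + 1, day, 1, rng)
        oviposit(s, p, rng)
    assert s.total_population.sum() == 0
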