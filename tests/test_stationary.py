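"""Phase plane of the single-sex model: first integral, periods, nucleus."""

import math

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from reintro import (
    EXTINCTION,
    Grid1D,
    IntegrationConfig,
    PERSISTENCE,
    PhasePoint,
    SingleSexParams,
    aperiodic_profile,
    first_integral,
    is_spreading_regime,
    maxwell_mortality,
    orbit_period,
    potential,
    run_single_sex,
    separatrix_constants,
    single_sex_rate,
    single_sex_roots,
)
from reintro.stationary import profile_residual


def test_potential_matches_quadrature(canonical_single):
    for u in np.linspace(0.0, 1.0, 100):
        val, _ = quad(lambda v: single_sex_rate(v, canonical_single), 0.0, u)
        assert abs(potential(u, canonical_single) - val) < 1e-10
    assert potential(0.0, canonical_single) == 0.0


def test_potential_critical_points_at_local_equilibria(canonical_single):
    h = 1e-7
    for u_star in single_sex_roots(canonical_single):
        dG = (potential(u_star + h, canonical_single) - potential(u_star - h, canonical_single)) / (2 * h)
        assert abs(dG) < 1e-10


def test_first_integral_constant_along_integrated_orbit(canonical_single):
    p = canonical_single
    u_lo, _ = single_sex_roots(p)
    # start inside the periodic band, off the center
    y0 = [u_lo * 1.3, 0.0]
    sol = solve_ivp(
        lambda x, y: [y[1], -single_sex_rate(max(y[0], 0.0), p) / p.D],
        (0.0, 200.0),
        y0,
        method="DOP853",
        rtol=1e-12,
        atol=1e-14,
        dense_output=True,
    )
    xs = np.linspace(0.0, 200.0, 400)
    E = np.array([first_integral(PhasePoint(*sol.sol(x)), p) for x in xs])
    assert np.std(E) / abs(np.mean(E)) < 1e-8


def test_fixed_point_first_integrals_and_classification(canonical_single):
    p = canonical_single
    cons = separatrix_constants(p)
    u_lo, u_hi = single_sex_roots(p)
    assert cons["extinction"]["E"] == 0.0
    assert cons["center"]["E"] == pytest.approx(potential(u_lo, p), abs=1e-15)
    assert cons["persistence"]["E"] == pytest.approx(potential(u_hi, p), abs=1e-15)
    assert cons["extinction"]["kind"] == "saddle"
    assert cons["persistence"]["kind"] == "saddle"
    assert cons["center"]["kind"] == "center"
    # the center sits at the potential minimum in the spreading regime
    assert cons["center"]["E"] < min(cons["extinction"]["E"], cons["persistence"]["E"])
    with pytest.raises(ValueError, match="bistable"):
        separatrix_constants(SingleSexParams(mu=0.07))


def test_orbit_period_harmonic_limit_and_divergence():
    p = SingleSexParams(mu=0.05, D=1.0)
    u_lo, _ = single_sex_roots(p)
    gp = (single_sex_rate(u_lo + 1e-7, p) - single_sex_rate(u_lo - 1e-7, p)) / 2e-7
    harmonic = 2.0 * math.pi * math.sqrt(p.D / gp)
    E_c = potential(u_lo, p)
    T_small = orbit_period(E_c * (1.0 - 1e-8), p)
    assert abs(T_small - harmonic) / harmonic < 1e-2  # period does NOT vanish
    # toward the separatrix the period grows without bound (log divergence)
    fracs = [1e-2, 1e-4, 1e-6, 1e-8, 1e-10]
    periods = [orbit_period(f * E_c, p) for f in fracs]
    assert all(t2 > t1 for t1, t2 in zip(periods, periods[1:]))
    increments = np.diff(periods)
    assert np.all(increments > 0.8 * increments[0])  # non-decaying growth per decade


def test_orbit_period_finite_across_band(canonical_single):
    E_c = potential(single_sex_roots(canonical_single)[0], canonical_single)
    for f in np.logspace(-6, -0.05, 12):
        T = orbit_period(E_c * f, canonical_single)
        assert np.isfinite(T) and T > 0.0
    with pytest.raises(ValueError, match="periodic band"):
        orbit_period(abs(E_c), canonical_single)


def test_spreading_regime_gate():
    assert is_spreading_regime(SingleSexParams(mu=0.05))
    mu_M = maxwell_mortality(SingleSexParams(mu=0.05))
    assert 0.0 < mu_M < 1.0 / 16.0
    assert not is_spreading_regime(SingleSexParams(mu=mu_M * 1.05))
    with pytest.raises(ValueError, match="non-spreading"):
        aperiodic_profile(SingleSexParams(mu=mu_M * 1.05))


def test_aperiodic_profile_solves_stationary_equation(canonical_single):
    prof = aperiodic_profile(canonical_single, threshold=1e-3, dx=0.05)
    res = profile_residual(prof, canonical_single)
    gmax = np.abs(single_sex_rate(np.linspace(0, 0.6, 300), canonical_single)).max()
    assert np.abs(res).max() < 1e-6 * gmax
    # symmetric about the peak, peak between the Allee and persistence roots
    u_lo, u_hi = single_sex_roots(canonical_single)
    assert np.abs(prof.u - prof.u[::-1]).max() < 1e-12
    assert u_lo < prof.u_max < u_hi
    assert abs(potential(prof.u_max, canonical_single)) < 1e-12


def test_profile_width_and_cost_double_under_4x_diffusion(canonical_single):
    small_thr = 1e-5  # near the threshold->0 limit the x->2x rescaling is exact
    p4 = SingleSexParams(mu=canonical_single.mu, D=4.0 * canonical_single.D)
    prof1 = aperiodic_profile(canonical_single, threshold=small_thr, dx=0.02)
    prof2 = aperiodic_profile(p4, threshold=small_thr, dx=0.04)
    assert prof2.width == pytest.approx(2.0 * prof1.width, rel=1e-3)
    assert prof2.cost == pytest.approx(2.0 * prof1.cost, rel=1e-3)


def test_profile_cost_monotone_and_convergent_in_threshold(canonical_single):
    thresholds = [3e-2, 1e-2, 1e-3, 1e-4, 1e-5]
    costs = [aperiodic_profile(canonical_single, threshold=t, dx=0.05).cost for t in thresholds]
    assert all(c2 >= c1 for c1, c2 in zip(costs, costs[1:]))  # cost grows as threshold shrinks
    # convergence: successive increments shrink rapidly
    inc = np.diff(costs)
    assert inc[-1] < 0.05 * inc[0]
    # the analytic tail estimate brackets the truncation error
    prof = aperiodic_profile(canonical_single, threshold=1e-3, dx=0.05)
    assert prof.cost < prof.cost_with_tail < prof.cost * 1.01


def test_nucleus_separates_extinction_from_persistence(canonical_single):
    """Scaling the marginal profile by +-1 percent flips the outcome."""
    prof = aperiodic_profile(canonical_single, threshold=1e-3, dx=0.1)
    pad = int(round(prof.width / 0.1))
    for scale, expected in [(1.01, PERSISTENCE), (0.99, EXTINCTION)]:
        u = np.concatenate([np.zeros(pad), scale * prof.u, np.zeros(pad)])
        grid = Grid1D(length=0.1 * (u.size - 1), n_points=u.size)
        _, out = run_single_sex(
            u, canonical_single, grid, IntegrationConfig(tol_converge=1e-6, max_time=4000.0)
        )
        assert out.label == expected


def test_orbit_classification_bands(canonical_single):
    from reintro import classify_orbit

    p = canonical_single
    E_center = potential(single_sex_roots(p)[0], p)
    assert classify_orbit(E_center, p).kind == "fixed_point"
    assert classify_orbit(0.0, p).kind == "aperiodic_separatrix"
    assert classify_orbit(0.5 * E_center, p).kind == "periodic"
    assert classify_orbit(2.0 * abs(E_center), p).kind == "unbounded"
    assert classify_orbit(1.5 * E_center, p).kind == "unbounded"  # below the center well
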