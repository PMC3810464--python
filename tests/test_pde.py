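"""Explicit-Euler integrator: fixed points, symmetry, classification, ordering."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from reintro import (
    EXTINCTION,
    Grid1D,
    IntegrationConfig,
    PERSISTENCE,
    StateField,
    equilibria,
    integrate_to_equilibrium,
    local_rates,
    run_single_sex,
    stable_dt,
    step,
)


@pytest.fixture(scope="module")
def grid():
    return Grid1D(length=80.0, n_points=321)


def test_homogeneous_equilibrium_is_fixed_point(canonical, grid):
    eq = equilibria(canonical)
    st = StateField.homogeneous(grid, *eq.persistence)
    st2 = step(st, canonical, grid, IntegrationConfig())
    assert np.abs(st2.f - st.f).max() < 1e-12
    assert np.abs(st2.m - st.m).max() < 1e-12
    zero = StateField.zeros(grid)
    z2 = step(zero, canonical, grid, IntegrationConfig())
    assert np.all(z2.f == 0.0) and np.all(z2.m == 0.0)


def test_step_preserves_sex_and_mirror_symmetry(canonical, grid):
    st = StateField.from_rectangles(grid, 0.3, 0.3, 12.0, 12.0)
    out = st
    for _ in range(50):
        out = step(out, canonical, grid, IntegrationConfig())
    assert np.array_equal(out.f, out.m)  # equation symmetry, exact
    assert np.abs(out.f - out.f[::-1]).max() < 1e-10  # mirror symmetry


def test_dt_stability_bound_enforced(canonical, grid):
    st = StateField.from_rectangles(grid, 0.3, 0.3, 12.0, 12.0)
    bad = IntegrationConfig(dt=grid.dx**2)  # exceeds dx^2/(2 max D) for D=1
    with pytest.raises(ValueError, match="stability bound"):
        step(st, canonical, grid, bad)


def test_nonnegativity_preserved(canonical, grid, rng):
    st = StateField(rng.uniform(0, 0.4, grid.n_points), rng.uniform(0, 0.4, grid.n_points))
    cfg = IntegrationConfig(tol_converge=1e-6, max_time=20.0, record_every=5.0)
    final, out = integrate_to_equilibrium(st, canonical, grid, cfg)
    for snap in out.snapshots:
        assert np.all(snap.f >= 0.0) and np.all(snap.m >= 0.0)


def _ode_outcome(f0, m0, params):
    """0-D oracle: long-time local dynamics from a homogeneous start."""
    sol = solve_ivp(
        lambda t, y: local_rates(max(y[0], 0.0), max(y[1], 0.0), params),
        (0.0, 5000.0),
        [f0, m0],
        method="LSODA",
        rtol=1e-10,
        atol=1e-13,
    )
    total = sol.y[0, -1] + sol.y[1, -1]
    eq = equilibria(params)
    return PERSISTENCE if abs(total - eq.persistence_total) < 0.1 * eq.persistence_total else EXTINCTION


@pytest.mark.parametrize("scale,expected_of", [(0.95, "allee"), (0.9, "persistence")])
def test_homogeneous_outcomes_match_local_ode_oracle(canonical, grid, scale, expected_of):
    eq = equilibria(canonical)
    base = eq.allee if expected_of == "allee" else eq.persistence
    f0, m0 = scale * base[0], scale * base[1]
    assert _ode_outcome(f0, m0, canonical) == (
        EXTINCTION if expected_of == "allee" else PERSISTENCE
    )
    st = StateField.homogeneous(grid, f0, m0)
    _, out = integrate_to_equilibrium(
        st, canonical, grid, IntegrationConfig(tol_converge=1e-6, max_time=3000.0)
    )
    assert out.label == _ode_outcome(f0, m0, canonical)


def test_supercritical_cluster_persists_at_two_resolutions(canonical):
    eq = equilibria(canonical)
    for n_points in (241, 481):
        grid = Grid1D(length=120.0, n_points=n_points)
        st = StateField.from_rectangles(grid, *eq.persistence, 46.0, 46.0)  # ~4x critical
        _, out = integrate_to_equilibrium(
            st, canonical, grid, IntegrationConfig(tol_converge=1e-6, max_time=3000.0)
        )
        assert out.label == PERSISTENCE


def test_single_sex_trajectory_matches_two_sex_reduction(canonical, canonical_single, grid):
    st = StateField.from_rectangles(grid, 0.36, 0.36, 9.0, 9.0)
    cfg = IntegrationConfig(tol_converge=1e-6, max_time=300.0, record_every=30.0)
    _, out2 = integrate_to_equilibrium(st, canonical, grid, cfg)
    u, out1 = run_single_sex(st.f.copy(), canonical_single, grid, cfg)
    assert len(out1.snapshots) == len(out2.snapshots)
    for s1, s2 in zip(out1.snapshots, out2.snapshots):
        assert np.abs(s1.f - s2.f).max() < 1e-10
    assert out1.label == out2.label


def test_single_sex_stationary_at_carrying_capacity(canonical_single, grid):
    from reintro import single_sex_roots

    _, u_hi = single_sex_roots(canonical_single)
    u0 = np.full(grid.n_points, u_hi)
    u, out = run_single_sex(u0, canonical_single, grid, IntegrationConfig(max_time=50.0))
    assert np.abs(u - u_hi).max() < 1e-12


def test_comparison_principle_orders_single_sex_solutions(canonical_single, grid):
    """Scalar parabolic comparison: ordered initial data stay ordered."""
    a = StateField.from_rectangles(grid, 0.36, 0.36, 14.0, 14.0).f
    b = StateField.from_rectangles(grid, 0.30, 0.30, 10.0, 10.0).f
    assert np.all(a >= b)
    cfg = IntegrationConfig(tol_converge=1e-6, max_time=200.0, record_every=20.0, early_exit=False)
    _, out_a = run_single_sex(a, canonical_single, grid, cfg)
    _, out_b = run_single_sex(b, canonical_single, grid, cfg)
    for sa, sb in zip(out_a.snapshots, out_b.snapshots):
        assert np.all(sa.f >= sb.f - 1e-12)


def test_rectangle_mass_equals_density_times_length(grid):
    st = StateField.from_rectangles(grid, 0.3, 0.25, 10.37, 7.91)
    assert st.f.sum() * grid.dx == pytest.approx(0.3 * 10.37, rel=1e-12)
    assert st.m.sum() * grid.dx == pytest.approx(0.25 * 7.91, rel=1e-12)
    with pytest.raises(ValueError, match="capacity"):
        StateField.from_rectangles(grid, 0.7, 0.7, 10.0, 10.0)
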