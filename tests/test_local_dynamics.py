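"""Closed-form local dynamics: fixed points, stability, optimal sex ratio."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from reintro import (
    ModelParams,
    SingleSexParams,
    equilibria,
    local_rates,
    optimal_sex_ratio,
    single_sex_rate,
    single_sex_roots,
    stability_condition_single_sex,
    stability_condition_two_sex,
    admissible_sex_ratio_interval,
)
from reintro.fixtures import random_admissible_params
from reintro.local_dynamics import local_jacobian


def test_no_females_means_pure_male_decay(canonical):
    df, dm = local_rates(0.0, 0.4, canonical)
    assert df == 0.0
    assert dm == pytest.approx(-canonical.mu_m * 0.4)
    assert local_rates(0.0, 0.0, canonical) == (0.0, 0.0)


def test_negative_densities_rejected(canonical):
    with pytest.raises(ValueError):
        local_rates(-0.1, 0.2, canonical)
    with pytest.raises(ValueError):
        single_sex_rate(-1e-9, canonical.to_single_sex())


def test_equilibria_zero_the_rates_and_are_ordered(rng):
    for p in random_admissible_params(rng, 50):
        eq = equilibria(p)
        assert eq.exists
        for pt in (eq.allee, eq.persistence):
            df, dm = local_rates(*pt, p)
            assert abs(df) < 1e-10 and abs(dm) < 1e-10
        assert 0.0 < eq.allee_total < eq.persistence_total < 1.0
        s_lo, s_hi = eq.s_values
        assert 0.0 < s_lo < s_hi < 1.0


@settings(derandomize=True, max_examples=200, deadline=None)
@given(
    r=st.floats(0.05, 0.95),
    mu_f=st.floats(0.001, 0.2),
    mu_m=st.floats(0.001, 0.2),
)
def test_stability_condition_agrees_with_root_existence(r, mu_f, mu_m):
    p = ModelParams(r=r, mu_f=mu_f, mu_m=mu_m)
    assert stability_condition_two_sex(p) == equilibria(p).exists


def test_stability_condition_examples():
    assert stability_condition_two_sex(ModelParams(r=0.5, mu_f=0.05, mu_m=0.05))
    # equality is not strict bistability
    assert not stability_condition_two_sex(ModelParams(r=0.5, mu_f=0.0625, mu_m=0.0625))
    # extreme sex-ratio bias: mortality load diverges
    assert not stability_condition_two_sex(ModelParams(r=1e-6, mu_f=0.05, mu_m=0.05))
    assert stability_condition_single_sex(SingleSexParams(mu=0.05))
    assert not stability_condition_single_sex(SingleSexParams(mu=0.0625))
    assert not stability_condition_single_sex(SingleSexParams(mu=0.1))


def test_symmetric_reduction_matches_single_sex_roots():
    for mu in (0.01, 0.03, 0.05, 0.06):
        p = ModelParams(r=0.5, mu_f=mu, mu_m=mu)
        eq = equilibria(p)
        u_lo, u_hi = single_sex_roots(p.to_single_sex())
        assert eq.allee[0] == pytest.approx(eq.allee[1], abs=1e-14)
        assert eq.allee[0] == pytest.approx(u_lo, abs=1e-12)
        assert eq.persistence[0] == pytest.approx(u_hi, abs=1e-12)


def test_single_sex_rate_equals_two_sex_diagonal(rng, canonical_single):
    p2 = canonical_single.to_two_sex()
    u = rng.uniform(0.0, 0.6, size=100)
    df, dm = local_rates(u, u, p2)
    g = single_sex_rate(u, canonical_single)
    np.testing.assert_allclose(df, g, atol=1e-15)
    np.testing.assert_allclose(dm, g, atol=1e-15)


def test_single_sex_rate_sign_structure(canonical_single):
    u_lo, u_hi = single_sex_roots(canonical_single)
    u_below = np.linspace(1e-4, u_lo * 0.999, 50)
    u_mid = np.linspace(u_lo * 1.001, u_hi * 0.999, 50)
    assert np.all(single_sex_rate(u_below, canonical_single) < 0)
    assert np.all(single_sex_rate(u_mid, canonical_single) > 0)


def test_jacobian_classifies_allee_unstable_persistence_stable(rng):
    for p in random_admissible_params(rng, 20):
        eq = equilibria(p)
        assert eq.persistence_stable
        assert not eq.allee_stable
        eig_allee = np.linalg.eigvals(local_jacobian(*eq.allee, p))
        assert np.max(eig_allee.real) > 0.0


def test_equilibria_match_long_time_ode(rng):
    """Closed-form persistence point agrees with the 0-D attractor."""
    for p in random_admissible_params(rng, 10):
        eq = equilibria(p)
        f0, m0 = eq.persistence
        sol = solve_ivp(
            lambda t, y: local_rates(max(y[0], 0.0), max(y[1], 0.0), p),
            (0.0, 3000.0),
            [1.05 * f0, 1.05 * m0],
            method="LSODA",
            rtol=1e-10,
            atol=1e-12,
        )
        assert abs(sol.y[0, -1] - f0) < 1e-6
        assert abs(sol.y[1, -1] - m0) < 1e-6


def test_optimal_sex_ratio_closed_form():
    assert optimal_sex_ratio(0.05, 0.05) == 0.5
    assert optimal_sex_ratio(0.04, 0.01) == pytest.approx(2.0 / 3.0, abs=1e-14)


def _grid_search_rstar(mu_f, mu_m, step=1e-4):
    r = np.arange(step, 1.0, step)
    A = mu_f / r + mu_m / (1.0 - r)
    dens = np.where(A < 0.25, 0.5 + np.sqrt(np.maximum(0.25 - A, 0.0)), -np.inf)
    return r[np.argmax(dens)]


def test_optimal_sex_ratio_matches_grid_argmax(rng):
    for _ in range(10):
        mu_f = rng.uniform(0.005, 0.05)
        mu_m = rng.uniform(0.005, 0.05)
        r_star = optimal_sex_ratio(mu_f, mu_m)
        assert abs(r_star - _grid_search_rstar(mu_f, mu_m)) < 1e-3
        lo, hi = admissible_sex_ratio_interval(mu_f, mu_m)
        assert lo < r_star < hi


def test_persistence_density_unimodal_in_r():
    mu_f, mu_m = 0.06, 0.02
    lo, hi = admissible_sex_ratio_interval(mu_f, mu_m)
    r = np.arange(lo + 1e-3, hi - 1e-3, 1e-3)
    dens = np.array(
        [equilibria(ModelParams(r=ri, mu_f=mu_f, mu_m=mu_m)).persistence_total for ri in r]
    )
    d = np.diff(dens)
    sign_changes = np.sum(np.diff(np.sign(d[d != 0])) != 0)
    assert sign_changes <= 1  # unimodal
    assert abs(r[np.argmax(dens)] - optimal_sex_ratio(mu_f, mu_m)) < 2e-3
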