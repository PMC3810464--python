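"""Phase-plane analysis of stationary solutions of the single-sex model.

Stationary profiles solve D u'' + g(u) = 0 with g the cubic local growth
rate.  Writing p = du/dx, the system (u, p) conserves the first integral

    E = (D/2) p^2 + G(u),        G(u) = int_0^u g(v) dv,

so orbits are level sets of E.  The local equilibria u=0 and u=u_plus are
saddles of the (u, p) system (stable nodes of the local dynamics) and the
Allee density u_minus is a center.  Closed orbits around the center are
spatially periodic stationary profiles; the homoclinic loop through the
origin saddle (E = 0, existing only in the spreading regime G(u_plus) > 0)
is the aperiodic "critical nucleus": the localized unstable profile that
separates collapsing from spreading initial conditions and whose area
gives a candidate restoration cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad, solve_ivp
from scipy.optimize import brentq

from .local_dynamics import single_sex_rate, single_sex_roots, stability_condition_single_sex
from .params import SingleSexParams

__all__ = [
    "PhasePoint",
    "OrbitClass",
    "classify_orbit",
    "StationaryProfile",
    "potential",
    "first_integral",
    "separatrix_constants",
    "orbit_period",
    "aperiodic_profile",
    "is_spreading_regime",
    "maxwell_mortality",
]


@dataclass(frozen=True)
class PhasePoint:
    u: float
    du_dx: float


@dataclass(frozen=True)
class OrbitClass:
    """Orbit family of a first-integral level set E."""

    E: float
    kind: str  # periodic | aperiodic_separatrix | unbounded | fixed_point


def classify_orbit(E: float, p: SingleSexParams, rtol: float = 1e-12) -> OrbitClass:
    """Classify the stationary-solution family at first integral E.

    Closed orbits around the center (periodic profiles) exist for E
    strictly between the center value G(u_minus) and the lower saddle
    level min(G(0), G(u_plus)); the saddle levels themselves carry the
    separatrices; everything else escapes to unbounded densities.
    """
    if not stability_condition_single_sex(p):
        raise ValueError("phase-plane structure requires the bistable regime mu < sigma/16")
    u_lo, u_hi = single_sex_roots(p)
    E_center = potential(u_lo, p)
    saddles = (0.0, potential(u_hi, p))
    scale = max(abs(E_center), 1e-300)
    if abs(E - E_center) <= rtol * scale:
        return OrbitClass(E, "fixed_point")
    if any(abs(E - Es) <= rtol * scale for Es in saddles):
        return OrbitClass(E, "aperiodic_separatrix")
    if E_center < E < min(saddles):
        return OrbitClass(E, "periodic")
    return OrbitClass(E, "unbounded")


@dataclass
class StationaryProfile:
    """Truncated aperiodic stationary profile, centered on its peak.

    cost counts both sexes (the symmetric reduction has f = m = u, so the
    total introduced population is twice the area under u).  cost_with_tail
    adds the analytic estimate of the two exponential tails removed by the
    density threshold.
    """

    x: np.ndarray
    u: np.ndarray
    threshold: float
    u_max: float
    E: float
    cost: float
    cost_with_tail: float

    @property
    def width(self) -> float:
        return float(self.x[-1] - self.x[0])


def potential(u, p: SingleSexParams):
    """G(u) = int_0^u g = sigma u^3/6 - sigma u^4/4 - mu u^2/2."""
    u = np.asarray(u, dtype=float)
    val = p.sigma * u**3 / 6.0 - p.sigma * u**4 / 4.0 - p.mu * u**2 / 2.0
    return float(val) if val.ndim == 0 else val


def first_integral(pt: PhasePoint, p: SingleSexParams) -> float:
    """E = (D/2)(du/dx)^2 + G(u), constant along stationary profiles."""
    return 0.5 * p.D * pt.du_dx**2 + potential(pt.u, p)


def _g_prime(u: float, p: SingleSexParams, h: float = 1e-7) -> float:
    return (single_sex_rate(u + h, p) - single_sex_rate(max(u - h, 0.0), p)) / (
        u + h - max(u - h, 0.0)
    )


def separatrix_constants(p: SingleSexParams) -> dict:
    """First-integral values and phase-plane type of each fixed point.

    Returns a dict keyed by role ('extinction', 'center', 'persistence')
    with entries {'u', 'E', 'kind'}; kind is 'saddle' or 'center' from the
    linearization eigenvalues +-sqrt(-g'(u*)/D).
    """
    if not stability_condition_single_sex(p):
        raise ValueError("phase-plane structure requires the bistable regime mu < sigma/16")
    u_lo, u_hi = single_sex_roots(p)
    out = {}
    for role, u_star in [("extinction", 0.0), ("center", u_lo), ("persistence", u_hi)]:
        gp = _g_prime(u_star, p)
        kind = "center" if gp > 0.0 else "saddle"
        out[role] = {"u": u_star, "E": potential(u_star, p), "kind": kind}
    return out


def maxwell_mortality(p: SingleSexParams, tol: float = 1e-12) -> float:
    """Mortality at which G(u_plus) = 0 (fronts stall), found numerically.

    Below this value fronts between extinction and persistence advance
    (spreading regime); between it and sigma/16 they recede and no finite
    introduction can restore the population.
    """

    def f(mu: float) -> float:
        q = SingleSexParams(mu=mu, D=p.D, sigma=p.sigma)
        return potential(single_sex_roots(q)[1], q)

    lo, hi = 1e-6 * p.sigma, p.sigma / 16.0 * (1.0 - 1e-9)
    return brentq(f, lo, hi, xtol=tol)


def is_spreading_regime(p: SingleSexParams) -> bool:
    """True when the homoclinic nucleus exists: bistable and G(u_plus) > 0."""
    if not stability_condition_single_sex(p):
        return False
    return potential(single_sex_roots(p)[1], p) > 0.0


def _turning_points(E: float, p: SingleSexParams) -> tuple[float, float]:
    u_lo, u_hi = single_sex_roots(p)
    E_center = potential(u_lo, p)
    E_sep = min(0.0, potential(u_hi, p))
    if not E_center < E < E_sep:
        raise ValueError(
            f"E={E} outside the periodic band ({E_center}, {E_sep})"
        )
    f = lambda u: potential(u, p) - E
    # G decreases on (0, u_minus) and increases on (u_minus, u_plus)
    u1 = brentq(f, 1e-15, u_lo, xtol=1e-15)
    u2 = brentq(f, u_lo, u_hi, xtol=1e-15)
    return u1, u2


def orbit_period(E: float, p: SingleSexParams) -> float:
    """Spatial period of the closed orbit with first integral E.

    The period 2 * int_{u1}^{u2} du / sqrt((2/D)(E - G(u))) is computed
    after the substitution u = c + a sin(theta), which removes the
    square-root singularities at the turning points:

        T = 2 * int_{-pi/2}^{pi/2} sqrt(D / (2 h(u))) dtheta,
        h(u) = (E - G(u)) / ((u - u1)(u2 - u)).

    As E approaches the center value the period tends to the harmonic
    limit 2 pi sqrt(D / g'(u_minus)), not to zero; toward the separatrix
    it diverges logarithmically.
    """
    u1, u2 = _turning_points(E, p)
    c, a = 0.5 * (u1 + u2), 0.5 * (u2 - u1)
    # endpoint limits of h: E - G ~ -g(u_i)(u - u_i)
    h1 = -single_sex_rate(u1, p) / (u2 - u1)
    h2 = single_sex_rate(u2, p) / (u2 - u1)

    def h(u: float) -> float:
        denom = (u - u1) * (u2 - u)
        if denom > 1e-6 * a * a:
            val = (E - potential(u, p)) / denom
            if val > 0.0:
                return val
        # near a turning point (or roundoff made E - G negative): use the
        # linearized endpoint value
        return h1 if abs(u - u1) < abs(u - u2) else h2

    integrand = lambda th: math.sqrt(p.D / (2.0 * h(c + a * math.sin(th))))
    val, _ = quad(integrand, -math.pi / 2.0, math.pi / 2.0, limit=200)
    return 2.0 * val


def _nucleus_peak(p: SingleSexParams) -> float:
    """Density u_max in (u_minus, u_plus) with G(u_max) = 0 (homoclinic apex)."""
    u_lo, u_hi = single_sex_roots(p)
    if potential(u_hi, p) <= 0.0:
        raise ValueError(
            "no homoclinic nucleus: G(u_plus) <= 0 (non-spreading regime); "
            "fronts recede and no finite introduction restores the population"
        )
    return brentq(lambda u: potential(u, p), u_lo * (1.0 + 1e-12), u_hi, xtol=1e-15)


def aperiodic_profile(
    p: SingleSexParams, threshold: float = 1e-3, dx: float = 0.05
) -> StationaryProfile:
    """Construct the aperiodic (homoclinic, E = 0) stationary profile.

    Integrates the stationary system u' = q, q' = -g(u)/D outward from the
    peak (where a fourth-order series step regularizes the square-root
    degeneracy of du/dx), stops at the density threshold, mirrors the half
    profile, and resamples on a uniform grid of spacing dx.  The cost is
    twice the trapezoidal area (both sexes).
    """
    if threshold <= 0.0:
        raise ValueError("threshold must be positive")
    u_max = _nucleus_peak(p)
    if threshold >= u_max:
        raise ValueError("threshold must be below the nucleus peak density")
    D = p.D
    g0 = single_sex_rate(u_max, p)
    gp0 = _g_prime(u_max, p)

    # series start just off the peak: u = u_max - g0 x^2/(2D) + g0 g0' x^4/(24 D^2)
    x0 = 1e-4 * math.sqrt(D / max(g0, 1e-30)) * math.sqrt(u_max)
    u_start = u_max - g0 * x0**2 / (2.0 * D) + g0 * gp0 * x0**4 / (24.0 * D * D)
    q_start = -g0 * x0 / D + g0 * gp0 * x0**3 / (6.0 * D * D)

    def rhs(x, y):
        return [y[1], -single_sex_rate(max(y[0], 0.0), p) / D]

    def hit_threshold(x, y):
        return y[0] - threshold

    hit_threshold.terminal = True
    hit_threshold.direction = -1

    # generous upper bound: core width plus tail decay length * log dynamic range
    x_span = 20.0 * math.sqrt(D / p.mu) + 10.0 * math.sqrt(D / max(g0, p.mu))
    sol = solve_ivp(
        rhs,
        (x0, x_span),
        [u_start, q_start],
        method="DOP853",
        rtol=1e-12,
        atol=1e-14,
        events=hit_threshold,
        dense_output=True,
    )
    if sol.t_events[0].size == 0:
        raise RuntimeError("profile integration failed to reach the density threshold")
    x_end = float(sol.t_events[0][0])

    n_half = max(int(math.ceil(x_end / dx)), 4)
    x_half = np.linspace(0.0, x_end, n_half + 1)
    u_half = np.empty_like(x_half)
    u_half[0] = u_max
    inner = x_half[1:] >= x0
    u_half[1:][inner] = sol.sol(x_half[1:][inner])[0]
    # points inside the series region (if any) use the series directly
    xs = x_half[1:][~inner]
    u_half[1:][~inner] = u_max - g0 * xs**2 / (2.0 * D) + g0 * gp0 * xs**4 / (24.0 * D * D)
    u_half = np.clip(u_half, 0.0, None)

    x = np.concatenate([-x_half[::-1], x_half[1:]])
    u = np.concatenate([u_half[::-1], u_half[1:]])
    cost = 2.0 * float(np.trapezoid(u, x))
    # exponential tails beyond the threshold: u ~ u_thr exp(-sqrt(mu/D) s)
    tail = 2.0 * 2.0 * u[-1] * math.sqrt(D / p.mu)
    return StationaryProfile(
        x=x,
        u=u,
        threshold=threshold,
        u_max=u_max,
        E=0.0,
        cost=cost,
        cost_with_tail=cost + tail,
    )


def profile_residual(profile: StationaryProfile, p: SingleSexParams) -> np.ndarray:
    """Interior residual D u'' + g(u) on a fourth-order 5-point stencil."""
    u, x = profile.u, profile.x
    dx = x[1] - x[0]
    upp = (-u[:-4] + 16.0 * u[1:-3] - 30.0 * u[2:-2] + 16.0 * u[3:-1] - u[4:]) / (
        12.0 * dx * dx
    )
    return p.D * upp + single_sex_rate(u[2:-2], p)
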