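"""Non-spatial (local) dynamics of the two-sex model.

The local system is

    df/dt = sigma * r * f * m * (1 - f - m) - mu_f * f
    dm/dt = sigma * (1-r) * f * m * (1 - f - m) - mu_m * m

i.e. males encounter females by mass action and the fraction of matings
producing offspring is the unoccupied fraction of the environment, so
growth is self-regulated.  Density-independent mortality acts on each sex.
The interplay of the bilinear birth term and mortality generates a strong
Allee effect: an unstable positive equilibrium separates extinction from
persistence.

This module provides the closed-form fixed points, the stability
conditions, and the density-maximizing sex ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .params import ModelParams, SingleSexParams

__all__ = [
    "EquilibriumSet",
    "local_rates",
    "single_sex_rate",
    "stability_condition_two_sex",
    "stability_condition_single_sex",
    "equilibria",
    "single_sex_roots",
    "optimal_sex_ratio",
    "admissible_sex_ratio_interval",
    "local_jacobian",
]


def local_rates(f, m, params: ModelParams):
    """Time derivatives (df/dt, dm/dt) of the local two-sex dynamics.

    Accepts scalars or numpy arrays.  Negative densities are rejected.
    """
    f = np.asarray(f, dtype=float)
    m = np.asarray(m, dtype=float)
    if np.any(f < 0.0) or np.any(m < 0.0):
        raise ValueError("densities must be non-negative")
    birth = params.sigma * f * m * (1.0 - f - m)
    df_dt = params.r * birth - params.mu_f * f
    dm_dt = (1.0 - params.r) * birth - params.mu_m * m
    if df_dt.ndim == 0:
        return float(df_dt), float(dm_dt)
    return df_dt, dm_dt


def single_sex_rate(u, p: SingleSexParams):
    """Local growth rate g(u) = (sigma/2) u^2 (1-2u) - mu u of the reduced model."""
    u = np.asarray(u, dtype=float)
    if np.any(u < 0.0):
        raise ValueError("density must be non-negative")
    g = 0.5 * p.sigma * u * u * (1.0 - 2.0 * u) - p.mu * u
    return float(g) if g.ndim == 0 else g


def stability_condition_two_sex(params: ModelParams) -> bool:
    """Whether a positive stable equilibrium exists: mu_f/r + mu_m/(1-r) < sigma/4."""
    return params.A < params.sigma / 4.0


def stability_condition_single_sex(p: SingleSexParams) -> bool:
    """Whether the cubic local dynamics is bistable: mu < sigma/16."""
    return p.mu < p.sigma / 16.0


def single_sex_roots(p: SingleSexParams) -> tuple[float, float]:
    """Positive roots (u_minus, u_plus) of g(u)=0.

    u_minus is the Allee threshold density, u_plus the persistence
    (carrying-capacity) density: u_pm = 1/4 -+ sqrt(1/16 - mu/sigma)
    (with sigma scaled out of the discriminant).
    """
    disc = 1.0 / 16.0 - p.mu / p.sigma
    if disc <= 0.0:
        raise ValueError("no positive equilibria: mu >= sigma/16")
    root = math.sqrt(disc)
    return 0.25 - root, 0.25 + root


def local_jacobian(f: float, m: float, params: ModelParams, step: float = 1e-7) -> np.ndarray:
    """Jacobian of local_rates at (f, m) by central differences."""
    jac = np.empty((2, 2))
    for j, (df_, dm_) in enumerate([(step, 0.0), (0.0, step)]):
        hi = local_rates(f + df_, m + dm_, params)
        lo = local_rates(max(f - df_, 0.0), max(m - dm_, 0.0), params)
        denom = (f + df_) - max(f - df_, 0.0) if j == 0 else (m + dm_) - max(m - dm_, 0.0)
        jac[0, j] = (hi[0] - lo[0]) / denom
        jac[1, j] = (hi[1] - lo[1]) / denom
    return jac


@dataclass(frozen=True)
class EquilibriumSet:
    """Fixed points of the local two-sex dynamics with stability labels.

    ``s_values`` are the two roots of the vacant-fraction equation
    s(1-s) = A/sigma; each maps to a positive fixed point
    (f*, m*) = (mu_m/((1-r) sigma s), mu_f/(r sigma s)).  The smaller
    root corresponds to the stable persistence state, the larger to the
    unstable Allee point.  Extinction (0, 0) always exists and is stable.
    """

    exists: bool
    extinction: tuple[float, float]
    allee: Optional[tuple[float, float]]
    persistence: Optional[tuple[float, float]]
    s_values: Optional[tuple[float, float]]
    allee_stable: Optional[bool] = None
    persistence_stable: Optional[bool] = None

    @property
    def allee_total(self) -> float:
        if self.allee is None:
            raise ValueError("no positive equilibria")
        return self.allee[0] + self.allee[1]

    @property
    def persistence_total(self) -> float:
        if self.persistence is None:
            raise ValueError("no positive equilibria")
        return self.persistence[0] + self.persistence[1]

    def to_dict(self) -> dict:
        return {
            "exists": self.exists,
            "extinction": list(self.extinction),
            "allee": list(self.allee) if self.allee else None,
            "persistence": list(self.persistence) if self.persistence else None,
            "s_values": list(self.s_values) if self.s_values else None,
            "allee_stable": self.allee_stable,
            "persistence_stable": self.persistence_stable,
        }


def _point_from_s(s: float, params: ModelParams) -> tuple[float, float]:
    f = params.mu_m / ((1.0 - params.r) * params.sigma * s)
    m = params.mu_f / (params.r * params.sigma * s)
    return f, m


def equilibria(params: ModelParams) -> EquilibriumSet:
    """Closed-form fixed points of the local dynamics with stability labels.

    Solves s(1-s) = A/sigma for the vacant fraction s.  Stability is
    classified from the numerically evaluated Jacobian eigenvalues rather
    than hand-derived formulas.
    """
    disc = 0.25 - params.A / params.sigma
    if disc <= 0.0:
        return EquilibriumSet(
            exists=False, extinction=(0.0, 0.0), allee=None, persistence=None, s_values=None
        )
    root = math.sqrt(disc)
    s_lo, s_hi = 0.5 - root, 0.5 + root  # small s = dense state
    persistence = _point_from_s(s_lo, params)
    allee = _point_from_s(s_hi, params)

    def _stable(pt: tuple[float, float]) -> bool:
        eig = np.linalg.eigvals(local_jacobian(pt[0], pt[1], params))
        return bool(np.all(eig.real < 0.0))

    return EquilibriumSet(
        exists=True,
        extinction=(0.0, 0.0),
        allee=allee,
        persistence=persistence,
        s_values=(s_lo, s_hi),
        allee_stable=_stable(allee),
        persistence_stable=_stable(persistence),
    )


def optimal_sex_ratio(mu_f: float, mu_m: float) -> float:
    """Sex ratio at birth maximizing the stable equilibrium total density.

    The persistence total density 1 - s decreases with the mortality load
    A(r) = mu_f/r + mu_m/(1-r), so the maximizer of density is the
    minimizer of A:  r* = sqrt(mu_f) / (sqrt(mu_f) + sqrt(mu_m)).
    """
    if mu_f <= 0.0 or mu_m <= 0.0:
        raise ValueError("mortality rates must be positive")
    sf, sm = math.sqrt(mu_f), math.sqrt(mu_m)
    return sf / (sf + sm)


def admissible_sex_ratio_interval(
    mu_f: float, mu_m: float, sigma: float = 1.0
) -> tuple[float, float]:
    """Open interval of sex ratios for which a positive stable equilibrium exists.

    Solves A(r) = sigma/4, i.e. the quadratic
    (sigma/4) r^2 - (sigma/4 + mu_f - mu_m) r + mu_f = 0.
    Raises if the interval is empty (mortalities too large).
    """
    a = sigma / 4.0
    b = -(sigma / 4.0 + mu_f - mu_m)
    c = mu_f
    disc = b * b - 4.0 * a * c
    if disc <= 0.0:
        raise ValueError("no admissible sex ratio: mortality load exceeds sigma/4 everywhere")
    root = math.sqrt(disc)
    r1 = (-b - root) / (2.0 * a)
    r2 = (-b + root) / (2.0 * a)
    lo, hi = min(r1, r2), max(r1, r2)
    return max(lo, 0.0), min(hi, 1.0)
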