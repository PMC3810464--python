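"""Critical cluster size and density for rectangular introductions.

A rectangular introduction places each sex at a homogeneous density inside
a centered cluster.  Because the local dynamics is bistable, the outcome
(persistence vs extinction) is monotone in cluster length at fixed density
and in density at fixed length, so both critical limits are found by
binary search over full PDE integrations.  The critical limits directly
give the minimum cost of assured restoration for this family of initial
conditions, since cost = n_f L_f + n_m L_m.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .local_dynamics import equilibria, optimal_sex_ratio, admissible_sex_ratio_interval
from .params import ModelParams
from .pde import (
    Grid1D,
    IntegrationConfig,
    PERSISTENCE,
    NOT_CONVERGED,
    StateField,
    integrate_to_equilibrium,
)

__all__ = [
    "DivergentSearch",
    "RectangularIC",
    "CriticalResult",
    "cost_rectangular",
    "critical_length",
    "critical_density",
    "scaling_exponent",
    "cost_vs_density_scan",
    "cost_vs_sex_ratio_scan",
    "search_config",
    "default_dx",
]

#: grid points per diffusion length sqrt(max D / min mu)
POINTS_PER_DIFFUSION_LENGTH = 16
#: upper search bound, in diffusion lengths
MAX_LENGTH_FACTOR = 50.0


class DivergentSearch(RuntimeError):
    """Binary search exhausted its bounds without finding a persistent state."""


@dataclass(frozen=True)
class RectangularIC:
    """Homogeneous clusters of each sex, centered at the habitat midpoint."""

    n_f: float
    n_m: float
    L_f: float
    L_m: float

    def __post_init__(self) -> None:
        if min(self.n_f, self.n_m, self.L_f, self.L_m) < 0.0:
            raise ValueError("densities and lengths must be non-negative")


@dataclass
class CriticalResult:
    """Outcome of a binary search for a critical length or density."""

    value: float
    bracket: tuple[float, float]
    evaluations: int
    grid: Grid1D
    resolution: float

    @property
    def bracket_width(self) -> float:
        return self.bracket[1] - self.bracket[0]


def cost_rectangular(ic: RectangularIC) -> float:
    """Restoration cost of a rectangular introduction: n_f L_f + n_m L_m."""
    return ic.n_f * ic.L_f + ic.n_m * ic.L_m


def default_dx(params: ModelParams) -> float:
    return params.diffusion_length() / POINTS_PER_DIFFUSION_LENGTH


def search_config() -> IntegrationConfig:
    """Integration controls used inside criticality searches."""
    return IntegrationConfig(tol_converge=1e-6, max_time=4000.0)


def _make_grid(habitat: float, dx: float) -> Grid1D:
    n = max(int(round(habitat / dx)) + 1, 16)
    return Grid1D(length=dx * (n - 1), n_points=n)


def _persists(
    ic: RectangularIC, params: ModelParams, grid: Grid1D, cfg: IntegrationConfig
) -> bool:
    state = StateField.from_rectangles(grid, ic.n_f, ic.n_m, ic.L_f, ic.L_m)
    _, outcome = integrate_to_equilibrium(state, params, grid, cfg)
    if outcome.label == NOT_CONVERGED:
        warnings.warn(
            f"integration did not converge for IC {ic}; treating as failed restoration",
            stacklevel=3,
        )
    return outcome.label == PERSISTENCE


def _require_above_allee(params: ModelParams, n_f: float, n_m: float):
    eq = equilibria(params)
    if not eq.exists:
        raise DivergentSearch(
            "no positive equilibria: the stability condition mu_f/r + mu_m/(1-r) < sigma/4 fails"
        )
    af, am = eq.allee
    if n_f <= af or n_m <= am:
        raise DivergentSearch(
            f"initial densities ({n_f:.4g}, {n_m:.4g}) must exceed the Allee "
            f"equilibrium ({af:.4g}, {am:.4g}) componentwise"
        )
    return eq


def critical_length(
    params: ModelParams,
    n_f: Optional[float] = None,
    n_m: Optional[float] = None,
    resolution: Optional[float] = None,
    dx: Optional[float] = None,
    cfg: Optional[IntegrationConfig] = None,
) -> CriticalResult:
    """Smallest equal cluster length restoring the population at the given densities.

    Densities default to the persistence-equilibrium densities.  The upper
    search bound is doubled from one diffusion length until a persistent
    length is found (capped at MAX_LENGTH_FACTOR diffusion lengths, beyond
    which DivergentSearch signals sub-threshold densities or the
    non-spreading regime); the habitat is then fixed at 6x that bound so
    boundaries stay inert, and the bracket is bisected to the requested
    resolution.
    """
    eq = equilibria(params)
    if n_f is None or n_m is None:
        if not eq.exists:
            raise DivergentSearch("no positive equilibria to take default densities from")
        n_f = eq.persistence[0] if n_f is None else n_f
        n_m = eq.persistence[1] if n_m is None else n_m
    _require_above_allee(params, n_f, n_m)
    ell = params.diffusion_length()
    dx = default_dx(params) if dx is None else dx
    resolution = dx if resolution is None else resolution
    cfg = search_config() if cfg is None else cfg

    evals = 0
    hi = ell
    while True:
        grid = _make_grid(6.0 * hi, dx)
        if _persists(RectangularIC(n_f, n_m, hi, hi), params, grid, cfg):
            evals += 1
            break
        evals += 1
        hi *= 2.0
        if hi > MAX_LENGTH_FACTOR * ell:
            raise DivergentSearch(
                f"no persistent cluster up to {MAX_LENGTH_FACTOR} diffusion lengths; "
                "densities may be too close to the Allee threshold or the "
                "parameters outside the spreading regime"
            )
    grid = _make_grid(6.0 * hi, dx)
    lo = 0.0  # vanishing cluster trivially fails
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if _persists(RectangularIC(n_f, n_m, mid, mid), params, grid, cfg):
            hi = mid
        else:
            lo = mid
        evals += 1
    return CriticalResult(0.5 * (lo + hi), (lo, hi), evals, grid, resolution)


def critical_density(
    params: ModelParams,
    L: float,
    resolution: float = 1e-3,
    split: Optional[float] = None,
    dx: Optional[float] = None,
    cfg: Optional[IntegrationConfig] = None,
) -> CriticalResult:
    """Lowest total density restoring the population in equal clusters of length L.

    The total density is divided between the sexes in a fixed proportion
    ``split`` = female share (default: the persistence-equilibrium
    proportion).  DivergentSearch is raised when even a near-saturated
    cluster fails, i.e. L is below the minimal nucleus width.
    """
    if L <= 0.0:
        raise ValueError("cluster length must be positive")
    eq = equilibria(params)
    if not eq.exists:
        raise DivergentSearch("no positive equilibria")
    if split is None:
        split = eq.persistence[0] / eq.persistence_total
    dx = default_dx(params) if dx is None else dx
    cfg = search_config() if cfg is None else cfg
    grid = _make_grid(6.0 * L, dx)

    def persists(total: float) -> bool:
        return _persists(
            RectangularIC(split * total, (1.0 - split) * total, L, L), params, grid, cfg
        )

    hi = 0.98
    evals = 1
    if not persists(hi):
        raise DivergentSearch(
            f"cluster of length {L} fails even at near-saturated density; "
            "L is below the minimal nucleus width"
        )
    lo = eq.allee_total  # homogeneous-limit lower bound: at/below it nothing grows
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if persists(mid):
            hi = mid
        else:
            lo = mid
        evals += 1
    return CriticalResult(0.5 * (lo + hi), (lo, hi), evals, grid, resolution)


def scaling_exponent(
    params: ModelParams,
    D_values,
    n_f: Optional[float] = None,
    n_m: Optional[float] = None,
    vary: str = "both",
    cfg: Optional[IntegrationConfig] = None,
) -> tuple[float, pd.DataFrame]:
    """Least-squares slope of log(critical length) vs log(D).

    ``vary`` selects which diffusion coefficient(s) follow D_values
    ('both', 'female' or 'male'); the grid spacing tracks the diffusion
    length so the relative search resolution is constant across the scan.
    Densities default to each parameter set's persistence equilibrium.
    """
    D_values = sorted(float(d) for d in D_values)
    if len(D_values) < 4:
        raise ValueError("need at least 4 diffusion values")
    rows = []
    for D in D_values:
        if vary == "both":
            p = replace(params, D_f=D, D_m=D)
        elif vary == "female":
            p = replace(params, D_f=D)
        elif vary == "male":
            p = replace(params, D_m=D)
        else:
            raise ValueError("vary must be 'both', 'female' or 'male'")
        res = critical_length(p, n_f, n_m, cfg=cfg)
        rows.append({"D": D, "critical_length": res.value, "evaluations": res.evaluations})
    table = pd.DataFrame(rows)
    slope = float(np.polyfit(np.log(table["D"]), np.log(table["critical_length"]), 1)[0])
    return slope, table


def cost_vs_density_scan(
    params: ModelParams,
    density_grid,
    split: Optional[float] = None,
    resolution: Optional[float] = None,
    dx: Optional[float] = None,
    cfg: Optional[IntegrationConfig] = None,
) -> tuple[pd.DataFrame, dict]:
    """Critical length and cost across initial total densities.

    Each total density is split between the sexes in a fixed proportion
    (default: persistence proportion).  Returns the table and a summary
    with the cost-minimizing density.
    """
    eq = equilibria(params)
    if not eq.exists:
        raise DivergentSearch("no positive equilibria")
    if split is None:
        split = eq.persistence[0] / eq.persistence_total
    rows = []
    for total in density_grid:
        n_f, n_m = split * total, (1.0 - split) * total
        res = critical_length(params, n_f, n_m, resolution=resolution, dx=dx, cfg=cfg)
        rows.append(
            {
                "total_density": float(total),
                "critical_length": res.value,
                "cost": total * res.value,
                "evaluations": res.evaluations,
            }
        )
    table = pd.DataFrame(rows)
    i = int(table["cost"].idxmin())
    summary = {
        "min_cost": float(table.loc[i, "cost"]),
        "argmin_density": float(table.loc[i, "total_density"]),
        "persistence_total": eq.persistence_total,
        "allee_total": eq.allee_total,
    }
    return table, summary


def cost_vs_sex_ratio_scan(
    mu_f: float,
    mu_m: float,
    D_f: float,
    D_m: float,
    r_grid,
    sigma: float = 1.0,
    resolution: Optional[float] = None,
    dx: Optional[float] = None,
    cfg: Optional[IntegrationConfig] = None,
) -> tuple[pd.DataFrame, dict]:
    """Critical cluster length and cost across sex ratios at birth.

    Initial densities are the r-dependent persistence-equilibrium
    densities.  The summary reports the cost-minimizing r together with a
    numerical error band: the contiguous range of scanned r whose cost
    lies within one binary-search cost quantum of the minimum.
    """
    r_lo, r_hi = admissible_sex_ratio_interval(mu_f, mu_m, sigma)
    rows = []
    for r in r_grid:
        r = float(r)
        if not r_lo < r < r_hi:
            continue
        p = ModelParams(r=r, mu_f=mu_f, mu_m=mu_m, D_f=D_f, D_m=D_m, sigma=sigma)
        eq = equilibria(p)
        n_f, n_m = eq.persistence
        res = critical_length(p, n_f, n_m, resolution=resolution, dx=dx, cfg=cfg)
        rows.append(
            {
                "r": r,
                "n_f": n_f,
                "n_m": n_m,
                "critical_length": res.value,
                "cost": (n_f + n_m) * res.value,
                "cost_error": (n_f + n_m) * res.bracket_width,
                "evaluations": res.evaluations,
            }
        )
    if not rows:
        raise ValueError("no admissible sex ratios in the grid")
    table = pd.DataFrame(rows).sort_values("r").reset_index(drop=True)
    i = int(table["cost"].idxmin())
    tol = float(table.loc[i, "cost_error"])
    within = table["cost"] <= table.loc[i, "cost"] + tol
    # contiguous band around the minimizer
    j_lo = i
    while j_lo > 0 and within[j_lo - 1]:
        j_lo -= 1
    j_hi = i
    while j_hi < len(table) - 1 and within[j_hi + 1]:
        j_hi += 1
    summary = {
        "r_min_cost": float(table.loc[i, "r"]),
        "band_lo": float(table.loc[j_lo, "r"]),
        "band_hi": float(table.loc[j_hi, "r"]),
        "r_optimal": optimal_sex_ratio(mu_f, mu_m),
        "admissible": (r_lo, r_hi),
        "min_cost": float(table.loc[i, "cost"]),
    }
    return table, summary
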