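"""1-D explicit-Euler integrator for the two-sex reaction-diffusion system.

Space is discretized with the standard second-order 3-point Laplacian on a
uniform grid; time with the explicit Euler method.  Integration stops when
the max-norm of the discrete time derivative drops below a tolerance, after
which the final state is classified as persistence or extinction by
comparison with the homogeneous equilibria of the local dynamics.

Two cheap early exits shortcut clearly decided runs: a collapsing state
whose peak total density falls below the extinction threshold, and a
spreading state whose total mass has grown well beyond any localized
critical structure while its peak sits on the persistence plateau.  Both
are classification shortcuts only; they never alter the scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np

from . import _kernels
from .local_dynamics import equilibria, single_sex_roots
from .params import ModelParams, SingleSexParams

__all__ = [
    "Grid1D",
    "StateField",
    "IntegrationConfig",
    "Outcome",
    "IntegrationDiverged",
    "stable_dt",
    "step",
    "integrate_to_equilibrium",
    "run_single_sex",
    "PERSISTENCE",
    "EXTINCTION",
    "NOT_CONVERGED",
]

PERSISTENCE = "PERSISTENCE"
EXTINCTION = "EXTINCTION"
NOT_CONVERGED = "NOT_CONVERGED"


class IntegrationDiverged(RuntimeError):
    """Raised when the explicit scheme produces non-finite values."""


@dataclass(frozen=True)
class Grid1D:
    """Uniform 1-D grid on [0, length] with n_points nodes."""

    length: float
    n_points: int
    boundary: str = "no-flux"

    def __post_init__(self) -> None:
        if self.n_points < 16:
            raise ValueError("n_points must be at least 16")
        if self.length <= 0.0:
            raise ValueError("length must be positive")
        if self.boundary not in ("no-flux", "absorbing"):
            raise ValueError(f"unknown boundary condition {self.boundary!r}")

    @property
    def dx(self) -> float:
        return self.length / (self.n_points - 1)

    @property
    def x(self) -> np.ndarray:
        return np.linspace(0.0, self.length, self.n_points)


@dataclass
class StateField:
    """Female and male density profiles on a grid, plus elapsed model time."""

    f: np.ndarray
    m: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.f = np.ascontiguousarray(self.f, dtype=float)
        self.m = np.ascontiguousarray(self.m, dtype=float)
        if self.f.shape != self.m.shape or self.f.ndim != 1:
            raise ValueError("f and m must be 1-D arrays of equal length")
        if np.any(self.f < 0.0) or np.any(self.m < 0.0):
            raise ValueError("densities must be non-negative")

    @classmethod
    def zeros(cls, grid: Grid1D) -> "StateField":
        return cls(np.zeros(grid.n_points), np.zeros(grid.n_points))

    @classmethod
    def homogeneous(cls, grid: Grid1D, f: float, m: float) -> "StateField":
        return cls(np.full(grid.n_points, f), np.full(grid.n_points, m))

    @classmethod
    def from_rectangles(
        cls,
        grid: Grid1D,
        n_f: float,
        n_m: float,
        L_f: float,
        L_m: float,
        check_simplex: bool = True,
    ) -> "StateField":
        """Centered rectangular clusters with fractional edge occupancy.

        Cluster lengths need not be multiples of dx: the two boundary nodes
        carry a partial weight so that the discrete mass equals density x
        length exactly, letting criticality vary continuously with L.
        """
        f = _rectangle(grid, n_f, L_f)
        m = _rectangle(grid, n_m, L_m)
        if check_simplex and np.any(f + m > 1.0 + 1e-9):
            raise ValueError("initial total density exceeds the habitat capacity f+m <= 1")
        return cls(f, m)

    def total(self) -> np.ndarray:
        return self.f + self.m

    def mass(self, grid: Grid1D) -> float:
        """Discrete total population (trapezoidal mass of f+m)."""
        return float(np.trapezoid(self.total(), dx=grid.dx))

    def copy(self) -> "StateField":
        return StateField(self.f.copy(), self.m.copy(), self.time)


def _rectangle(grid: Grid1D, density: float, L: float) -> np.ndarray:
    """Centered top-hat of the given length with fractional edge weights."""
    if density < 0.0 or L < 0.0:
        raise ValueError("density and length must be non-negative")
    u = np.zeros(grid.n_points)
    if density == 0.0 or L == 0.0:
        return u
    if L > grid.length:
        raise ValueError("cluster longer than the habitat")
    dx = grid.dx
    c = grid.length / 2.0
    lo, hi = c - L / 2.0, c + L / 2.0
    # each node represents the cell [x-dx/2, x+dx/2)
    for i, x in enumerate(grid.x):
        a = max(x - dx / 2.0, lo)
        b = min(x + dx / 2.0, hi)
        if b > a:
            u[i] = density * (b - a) / dx
    return u


@dataclass(frozen=True)
class IntegrationConfig:
    """Numerical controls for the explicit-Euler integration.

    dt=None selects the stability-limited step
    min(safety*dx^2/(2 max D), 0.1/(sigma + max mu)).  tol_converge is the
    max-norm time-derivative threshold declaring equilibrium.  The
    persistence band and extinction threshold classify the converged state;
    both are decisions, not model quantities, since any band separating the
    bistable attractors works.
    """

    dt: Optional[float] = None
    tol_converge: float = 1e-8
    max_time: float = 5000.0
    record_every: float = 0.0
    safety: float = 0.2
    ext_threshold: float = 1e-4
    persist_band: float = 0.10
    early_exit: bool = True

    def __post_init__(self) -> None:
        if self.tol_converge <= 0.0:
            raise ValueError("tol_converge must be positive")
        if not 0.0 < self.safety <= 1.0:
            raise ValueError("safety must be in (0, 1]")


@dataclass
class Outcome:
    label: str
    final_mean_density: float
    elapsed_time: float
    max_derivative: float = math.nan
    steps: int = 0
    snapshots: Optional[List[StateField]] = field(default=None, repr=False)


def stable_dt(grid: Grid1D, params: ModelParams, safety: float = 0.2) -> float:
    """Explicit-Euler step obeying the diffusive CFL bound and a reaction cap."""
    max_d = max(params.D_f, params.D_m)
    react = 0.1 / (params.sigma + max(params.mu_f, params.mu_m))
    if max_d <= 0.0:
        return react
    return min(safety * grid.dx ** 2 / (2.0 * max_d), react)


def _check_dt(dt: float, grid: Grid1D, params: ModelParams) -> None:
    max_d = max(params.D_f, params.D_m)
    if max_d > 0.0 and dt > grid.dx ** 2 / (2.0 * max_d) * (1.0 + 1e-12):
        raise ValueError("dt violates the explicit-Euler diffusive stability bound")


def _support_width(total: np.ndarray, grid: Grid1D, eps: float = 1e-12) -> float:
    idx = np.flatnonzero(total > eps)
    if idx.size == 0:
        return 0.0
    return (idx[-1] - idx[0] + 1) * grid.dx


def _early_exit_thresholds(
    state: StateField, params: ModelParams, grid: Grid1D, cfg: IntegrationConfig
):
    """(persist_mass, peak_lo, peak_hi) for the kernel's spreading shortcut."""
    if not cfg.early_exit:
        return -1.0, 0.0, 0.0
    eq = equilibria(params)
    if not eq.exists:
        return -1.0, 0.0, 0.0
    pt = eq.persistence_total
    ell = params.diffusion_length()
    support = _support_width(state.total(), grid)
    mass = pt * (support + 8.0 * ell)
    mass = min(mass, 0.5 * grid.length * pt)
    return mass, 0.9 * pt, 1.1 * pt


def _classify(
    mean_total: float, code: int, params: ModelParams, cfg: IntegrationConfig
) -> str:
    if code == 0:
        return PERSISTENCE
    if code == 1:
        return EXTINCTION
    if code == 2:
        eq = equilibria(params)
        if eq.exists:
            pt = eq.persistence_total
            if abs(mean_total - pt) <= cfg.persist_band * pt:
                return PERSISTENCE
        if mean_total < cfg.ext_threshold:
            return EXTINCTION
        return NOT_CONVERGED
    return NOT_CONVERGED


def step(
    state: StateField, params: ModelParams, grid: Grid1D, cfg: IntegrationConfig
) -> StateField:
    """One explicit-Euler step; returns a new StateField."""
    dt = cfg.dt if cfg.dt is not None else stable_dt(grid, params, cfg.safety)
    _check_dt(dt, grid, params)
    f, m, t, code, maxd, _ = _kernels.run_two_sex(
        state.f.copy(),
        state.m.copy(),
        grid.dx,
        dt,
        params.r,
        params.mu_f,
        params.mu_m,
        params.sigma,
        params.D_f,
        params.D_m,
        grid.boundary == "absorbing",
        -1.0,
        state.time,
        math.inf,
        1,
        1,
        -1.0,
        -1.0,
        0.0,
        0.0,
    )
    if code == 9:
        raise IntegrationDiverged(f"non-finite values after one step (max derivative {maxd})")
    return StateField(f, m, t)


def integrate_to_equilibrium(
    state: StateField, params: ModelParams, grid: Grid1D, cfg: IntegrationConfig
) -> tuple[StateField, Outcome]:
    """Integrate until equilibrium, a decisive early exit, or max_time.

    With cfg.record_every > 0 the returned Outcome carries snapshots of the
    state at that cadence (plus the final state).
    """
    if state.f.shape[0] != grid.n_points:
        raise ValueError("state does not match grid")
    dt = cfg.dt if cfg.dt is not None else stable_dt(grid, params, cfg.safety)
    _check_dt(dt, grid, params)
    check_every = max(1, int(round(0.5 / dt)))
    persist_mass, peak_lo, peak_hi = _early_exit_thresholds(state, params, grid, cfg)

    f, m = state.f.copy(), state.m.copy()
    t = state.time
    snapshots: Optional[List[StateField]] = [] if cfg.record_every > 0.0 else None
    total_steps = 0
    if snapshots is not None:
        snapshots.append(StateField(f.copy(), m.copy(), t))
    while True:
        chunk_end = (
            min(t + cfg.record_every, cfg.max_time) if snapshots is not None else cfg.max_time
        )
        f, m, t, code, maxd, steps = _kernels.run_two_sex(
            f,
            m,
            grid.dx,
            dt,
            params.r,
            params.mu_f,
            params.mu_m,
            params.sigma,
            params.D_f,
            params.D_m,
            grid.boundary == "absorbing",
            cfg.tol_converge,
            t,
            chunk_end,
            2**62,
            check_every,
            cfg.ext_threshold,
            persist_mass,
            peak_lo,
            peak_hi,
        )
        total_steps += steps
        if snapshots is not None:
            snapshots.append(StateField(f.copy(), m.copy(), t))
        if code == 9:
            raise IntegrationDiverged(
                f"integration diverged at t={t:.4g} (max derivative {maxd:.3g}); "
                "reduce dt or check parameters"
            )
        if code != 3 or t >= cfg.max_time - 1e-9 * max(1.0, cfg.max_time):
            break
    final = StateField(f, m, t)
    mean_total = float(np.mean(final.total()))
    label = _classify(mean_total, code, params, cfg)
    return final, Outcome(label, mean_total, t, maxd, total_steps, snapshots)


def run_single_sex(
    u0: np.ndarray, p: SingleSexParams, grid: Grid1D, cfg: IntegrationConfig
) -> tuple[np.ndarray, Outcome]:
    """Integrate the reduced scalar equation u_t = D u_xx + g(u).

    Classification thresholds refer to the total two-sex density 2u so the
    outcome labels are directly comparable with the two-sex integrator
    under the symmetric reduction.
    """
    u = np.ascontiguousarray(u0, dtype=float).copy()
    if u.shape[0] != grid.n_points:
        raise ValueError("u0 does not match grid")
    if np.any(u < 0.0):
        raise ValueError("densities must be non-negative")
    two = p.to_two_sex()
    dt = cfg.dt if cfg.dt is not None else stable_dt(grid, two, cfg.safety)
    _check_dt(dt, grid, two)
    check_every = max(1, int(round(0.5 / dt)))
    proxy = StateField(u.copy(), u.copy())
    persist_mass, peak_lo, peak_hi = _early_exit_thresholds(proxy, two, grid, cfg)

    t = 0.0
    snapshots: Optional[List[StateField]] = [] if cfg.record_every > 0.0 else None
    total_steps = 0
    if snapshots is not None:
        snapshots.append(StateField(u.copy(), u.copy(), t))
    while True:
        chunk_end = (
            min(t + cfg.record_every, cfg.max_time) if snapshots is not None else cfg.max_time
        )
        u, t, code, maxd, steps = _kernels.run_single_sex(
            u,
            grid.dx,
            dt,
            p.mu,
            p.sigma,
            p.D,
            grid.boundary == "absorbing",
            cfg.tol_converge,
            t,
            chunk_end,
            2**62,
            check_every,
            cfg.ext_threshold,
            persist_mass,
            peak_lo,
            peak_hi,
        )
        total_steps += steps
        if snapshots is not None:
            snapshots.append(StateField(u.copy(), u.copy(), t))
        if code == 9:
            raise IntegrationDiverged(
                f"single-sex integration diverged at t={t:.4g} (max derivative {maxd:.3g})"
            )
        if code != 3 or t >= cfg.max_time - 1e-9 * max(1.0, cfg.max_time):
            break
    mean_total = float(np.mean(2.0 * u))
    label = _classify(mean_total, code, two, cfg)
    return u, Outcome(label, mean_total, t, maxd, total_steps, snapshots)
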