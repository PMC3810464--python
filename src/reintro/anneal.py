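"""Simulated annealing over discretized initial density shapes.

The initial distribution of each sex is a free non-negative function on
the PDE grid, making the cost a finite-dimensional function of the two
shape vectors instead of a functional.  A Metropolis chain perturbs the
shapes (point changes plus random growth/shrinkage of the support), and
every candidate accepted on cost must additionally pass the restoration
constraint, verified by a full PDE integration.  Visited costs follow a
Boltzmann distribution at a temperature-like parameter that is lowered
geometrically, so the expected cost decreases stage by stage; the best
feasible state ever visited is returned (no claim of global optimality
under a finite schedule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd

from .params import ModelParams
from .pde import (
    Grid1D,
    IntegrationConfig,
    PERSISTENCE,
    NOT_CONVERGED,
    StateField,
    integrate_to_equilibrium,
)

__all__ = ["ShapeState", "AnnealConfig", "propose", "feasible", "anneal"]


@dataclass
class ShapeState:
    """Sex-specific initial density shapes on a grid, with their cost."""

    f: np.ndarray
    m: np.ndarray
    dx: float
    cost: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        self.m = np.asarray(self.m, dtype=float)
        if np.any(self.f < 0.0) or np.any(self.m < 0.0):
            raise ValueError("shape densities must be non-negative")
        if self.cost is None:
            self.cost = self.compute_cost()

    def compute_cost(self) -> float:
        return float((self.f.sum() + self.m.sum()) * self.dx)

    def support(self, sex: str) -> tuple[int, int]:
        """Inclusive index range of nonzero entries of one sex (or (-1,-1))."""
        arr = self.f if sex == "f" else self.m
        idx = np.flatnonzero(arr > 0.0)
        if idx.size == 0:
            return -1, -1
        return int(idx[0]), int(idx[-1])

    def copy(self) -> "ShapeState":
        return ShapeState(self.f.copy(), self.m.copy(), self.dx, self.cost)

    @classmethod
    def from_rectangles(
        cls, grid: Grid1D, n_f: float, n_m: float, L_f: float, L_m: float
    ) -> "ShapeState":
        state = StateField.from_rectangles(grid, n_f, n_m, L_f, L_m)
        return cls(state.f, state.m, grid.dx)


@dataclass(frozen=True)
class AnnealConfig:
    """Annealing schedule and move set.

    T0=None sets the initial temperature to the standard deviation of the
    cost change over 100 random proposals from the initial state.  Cooling
    is geometric per stage; the chain stops when the per-stage acceptance
    rate falls below min_acceptance or after max_stages.
    """

    T0: Optional[float] = None
    cooling: float = 0.95
    moves_per_stage: int = 200
    move_amplitude: float = 0.05
    seed: int = 0
    max_stages: int = 60
    infeasible_policy: str = "reject"
    min_acceptance: float = 0.01
    p_perturb: float = 0.8
    p_grow: float = 0.1
    p_shrink: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 < self.cooling < 1.0:
            raise ValueError("cooling must be in (0, 1)")
        if self.move_amplitude < 0.0:
            raise ValueError("move_amplitude must be non-negative")
        if self.infeasible_policy not in ("reject", "penalize"):
            raise ValueError("infeasible_policy must be 'reject' or 'penalize'")
        if abs(self.p_perturb + self.p_grow + self.p_shrink - 1.0) > 1e-12:
            raise ValueError("move probabilities must sum to 1")


def propose(state: ShapeState, rng: np.random.Generator, cfg: AnnealConfig) -> ShapeState:
    """One random shape change: perturb a site, or grow/shrink the support."""
    a = cfg.move_amplitude
    if a == 0.0:
        return state.copy()
    new = state.copy()
    sex = "f" if rng.random() < 0.5 else "m"
    arr = new.f if sex == "f" else new.m
    other = new.m if sex == "f" else new.f
    i0, i1 = new.support(sex)
    u = rng.random()
    if i0 < 0 or u < cfg.p_perturb:
        if i0 < 0:  # empty support: seed one cell at the habitat center
            j = arr.size // 2
            arr[j] = rng.uniform(0.0, a)
        else:
            j = int(rng.integers(i0, i1 + 1))
            arr[j] = np.clip(arr[j] + rng.uniform(-a, a), 0.0, 1.0 - other[j])
    elif u < cfg.p_perturb + cfg.p_grow:
        left = rng.random() < 0.5
        j = i0 - 1 if left else i1 + 1
        if 0 <= j < arr.size:
            arr[j] = min(rng.uniform(0.0, a), 1.0 - other[j])
    else:
        j = i0 if rng.random() < 0.5 else i1
        arr[j] = 0.0
    new.cost = new.compute_cost()
    return new


def feasible(
    state: ShapeState, params: ModelParams, grid: Grid1D, cfg: IntegrationConfig
) -> bool:
    """Whether the shape, used as initial condition, restores the population."""
    field_ = StateField(state.f.copy(), state.m.copy())
    _, outcome = integrate_to_equilibrium(field_, params, grid, cfg)
    if outcome.label == NOT_CONVERGED:
        warnings.warn("feasibility run did not converge; treating as infeasible", stacklevel=2)
    return outcome.label == PERSISTENCE


def _auto_T0(init: ShapeState, rng: np.random.Generator, cfg: AnnealConfig) -> float:
    deltas = []
    for _ in range(100):
        prop = propose(init, rng, cfg)
        deltas.append(prop.cost - init.cost)
    s = float(np.std(deltas))
    return s if s > 0.0 else max(cfg.move_amplitude * init.dx, 1e-6)


def anneal(
    params: ModelParams,
    grid: Grid1D,
    cfg: AnnealConfig,
    init: ShapeState,
    pde_cfg: Optional[IntegrationConfig] = None,
) -> tuple[ShapeState, pd.DataFrame]:
    """Minimize the restoration cost over initial shapes by Metropolis annealing.

    The chain starts from a feasible state (raises otherwise).  A proposal
    is first screened by the Metropolis rule min(1, exp(-dC/T)) on its
    cost change, then its feasibility is verified by PDE integration;
    infeasible proposals are rejected outright under the default policy
    (or carried with a large cost penalty under 'penalize').  Returns the
    best feasible state visited and the per-stage trace.
    """
    if pde_cfg is None:
        pde_cfg = IntegrationConfig(tol_converge=1e-6, max_time=3000.0)
    if init.f.size != grid.n_points:
        raise ValueError("initial shape does not match grid")
    if not feasible(init, params, grid, pde_cfg):
        raise ValueError("initial shape must satisfy the restoration constraint")
    rng = np.random.default_rng(cfg.seed)
    T = cfg.T0 if cfg.T0 is not None else _auto_T0(init, rng, cfg)
    penalty = 5.0 * init.cost

    current = init.copy()
    current_feasible = True
    best = init.copy()
    rows = []
    for stage in range(cfg.max_stages):
        accepted = 0
        pde_runs = 0
        for _ in range(cfg.moves_per_stage):
            prop = propose(current, rng, cfg)
            cur_eff = current.cost + (0.0 if current_feasible else penalty)
            d_cost = prop.cost - cur_eff
            if d_cost > 0.0 and rng.random() >= np.exp(-d_cost / T):
                continue
            pde_runs += 1
            ok = feasible(prop, params, grid, pde_cfg)
            if not ok and cfg.infeasible_policy == "reject":
                continue
            if not ok:  # penalize: re-test the Metropolis rule with the penalty
                d_pen = prop.cost + penalty - cur_eff
                if d_pen > 0.0 and rng.random() >= np.exp(-d_pen / T):
                    continue
            current = prop
            current_feasible = ok
            accepted += 1
            if ok and prop.cost < best.cost:
                best = prop.copy()
        rate = accepted / cfg.moves_per_stage
        rows.append(
            {
                "stage": stage,
                "temperature": T,
                "acceptance_rate": rate,
                "current_cost": current.cost,
                "best_cost": best.cost,
                "pde_runs": pde_runs,
            }
        )
        if rate < cfg.min_acceptance:
            break
        T *= cfg.cooling
    if not feasible(best, params, grid, pde_cfg):  # re-verify on a fresh integration
        raise RuntimeError("best annealed state failed feasibility re-verification")
    return best, pd.DataFrame(rows)
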