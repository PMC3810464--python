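"""Cost minimization with sex-specific rectangular cluster lengths.

The equal-cluster constraint is relaxed: for a fixed female cluster length
L_f, binary search finds the critical male length L_m(L_f), defining a
one-dimensional cost C(L_f) = n_f L_f + n_m L_m(L_f).  Unit-step gradient
descent on L_f (one search-resolution unit per move, continuing through
flat stretches caused by discretization) locates the minimum, relying on
the convexity of the cost in the two cluster lengths.  At the
density-maximizing sex ratio the descent finds no improvement; away from
it, sex-specific cluster sizes lower the cost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional

from .cluster import (
    CriticalResult,
    DivergentSearch,
    MAX_LENGTH_FACTOR,
    RectangularIC,
    _make_grid,
    _persists,
    _require_above_allee,
    critical_length,
    default_dx,
    search_config,
)
from .params import ModelParams
from .pde import Grid1D, IntegrationConfig

__all__ = ["UnequalOptimum", "critical_male_length", "optimize_unequal"]


@dataclass
class UnequalOptimum:
    """Result of the sex-specific cluster-length descent."""

    L_f_opt: float
    L_m_opt: float
    cost: float
    cost_equal: float
    ratio: float
    trace: List[tuple[float, float, float]] = field(default_factory=list)
    evaluations: int = 0
    convex: bool = True


def critical_male_length(
    params: ModelParams,
    n_f: float,
    n_m: float,
    L_f: float,
    resolution: Optional[float] = None,
    dx: Optional[float] = None,
    cfg: Optional[IntegrationConfig] = None,
    grid: Optional[Grid1D] = None,
    hint: Optional[float] = None,
) -> CriticalResult:
    """Critical male cluster length at a fixed female cluster length.

    ``hint`` warm-starts the bracket near a previously found critical
    length (used by the descent, where consecutive L_f differ by one
    resolution unit).
    """
    if L_f <= 0.0:
        raise ValueError("L_f must be positive")
    _require_above_allee(params, n_f, n_m)
    ell = params.diffusion_length()
    dx = default_dx(params) if dx is None else dx
    resolution = dx if resolution is None else resolution
    cfg = search_config() if cfg is None else cfg

    evals = 0

    def persists(L_m: float, g: Grid1D) -> bool:
        nonlocal evals
        evals += 1
        return _persists(RectangularIC(n_f, n_m, L_f, L_m), params, g, cfg)

    # establish a persistent upper bound
    hi = hint if hint is not None else max(L_f, ell)
    lo = 0.0
    cap = MAX_LENGTH_FACTOR * ell
    if grid is None:
        grid = _make_grid(6.0 * max(L_f, hi), dx)
    while True:
        if 6.0 * max(L_f, hi) > grid.length * (1.0 + 1e-9):
            grid = _make_grid(6.0 * max(L_f, hi), dx)
        if persists(hi, grid):
            break
        lo = hi
        hi *= 2.0
        if hi > cap:
            raise DivergentSearch(
                f"no male cluster length up to {MAX_LENGTH_FACTOR} diffusion lengths "
                f"rescues the population at L_f={L_f:.4g}"
            )
    if hint is not None and lo == 0.0:
        # tighten from below: the hint may sit far above the true critical value
        probe = 0.5 * hi
        while probe > resolution and persists(probe, grid):
            hi = probe
            probe *= 0.5
        lo = probe if probe > resolution else 0.0
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if persists(mid, grid):
            hi = mid
        else:
            lo = mid
    return CriticalResult(0.5 * (lo + hi), (lo, hi), evals, grid, resolution)


def optimize_unequal(
    params: ModelParams,
    n_f: Optional[float] = None,
    n_m: Optional[float] = None,
    resolution: Optional[float] = None,
    dx: Optional[float] = None,
    step: Optional[float] = None,
    cfg: Optional[IntegrationConfig] = None,
    patience: int = 3,
    max_moves: int = 200,
) -> UnequalOptimum:
    """Minimize n_f L_f + n_m L_m(L_f) by unit-step descent on L_f.

    Starts from the equal-cluster critical length, probes both directions,
    then keeps stepping in the improving direction -- also across zero
    local gradients, which arise from discretization -- until the cost has
    exceeded the best value for ``patience`` consecutive moves.  Returns
    the best visited point; the cost ratio is relative to the
    equal-cluster cost (n_f + n_m) L_c.

    ``step`` is the descent move on L_f (default: one grid unit dx);
    ``resolution`` controls the inner binary searches and may be finer
    than the step, since fractional edge cells make cluster lengths
    continuous on the grid.
    """
    from .local_dynamics import equilibria

    eq = equilibria(params)
    if n_f is None or n_m is None:
        if not eq.exists:
            raise DivergentSearch("no positive equilibria to take default densities from")
        n_f = eq.persistence[0] if n_f is None else n_f
        n_m = eq.persistence[1] if n_m is None else n_m
    dx = default_dx(params) if dx is None else dx
    resolution = dx if resolution is None else resolution
    step = dx if step is None else step
    cfg = search_config() if cfg is None else cfg

    eq_res = critical_length(params, n_f, n_m, resolution=resolution, dx=dx, cfg=cfg)
    L0 = eq_res.value
    cost_equal = (n_f + n_m) * L0
    grid = _make_grid(8.0 * max(L0, params.diffusion_length()), dx)
    evals = eq_res.evaluations
    trace: List[tuple[float, float, float]] = []

    def cost_at(L_f: float, hint: Optional[float]) -> tuple[float, float]:
        nonlocal evals
        res = critical_male_length(
            params, n_f, n_m, L_f, resolution=resolution, dx=dx, cfg=cfg, grid=grid, hint=hint
        )
        evals += res.evaluations
        c = n_f * L_f + n_m * res.value
        trace.append((L_f, res.value, c))
        return c, res.value

    c0, Lm0 = cost_at(L0, hint=L0)
    best = (L0, Lm0, c0)

    # probe both directions; follow the lower cost
    c_minus, Lm_minus = cost_at(L0 - step, hint=Lm0) if L0 - step > 0 else (float("inf"), Lm0)
    c_plus, Lm_plus = cost_at(L0 + step, hint=Lm0)
    if c_minus <= c_plus:
        direction, L_f, cost, L_m = -1.0, L0 - step, c_minus, Lm_minus
    else:
        direction, L_f, cost, L_m = 1.0, L0 + step, c_plus, Lm_plus
    if cost < best[2]:
        best = (L_f, L_m, cost)

    rises = 0
    for _ in range(max_moves):
        L_next = L_f + direction * step
        if L_next <= 0.0:
            break
        try:
            c, L_m = cost_at(L_next, hint=L_m)
        except DivergentSearch:
            break
        L_f = L_next
        if c < best[2]:
            best = (L_f, L_m, c)
            rises = 0
        else:
            rises += 1
            if rises >= patience:
                break

    # convexity check on the visited costs along the descent direction
    quantum = 2.0 * max(n_f, n_m) * max(resolution, step)
    costs = [t[2] for t in trace[2:]]  # skip the two initial probes
    convex = True
    running_min = float("inf")
    rose = False
    for c in costs:
        if c > running_min + quantum:
            rose = True
        if rose and c < running_min - quantum:
            convex = False
        running_min = min(running_min, c)
    if not convex:
        warnings.warn("cost trace rose then fell: cost may not be convex in L_f", stacklevel=2)

    return UnequalOptimum(
        L_f_opt=best[0],
        L_m_opt=best[1],
        cost=best[2],
        cost_equal=cost_equal,
        ratio=best[2] / cost_equal,
        trace=trace,
        evaluations=evals,
        convex=convex,
    )
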