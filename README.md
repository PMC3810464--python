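# reintro

Cost-optimal planning of species reintroductions in a **two-sex
reaction–diffusion model with a strong Allee effect**.

When a species is reintroduced into a large habitat, releasing too few
individuals — or spreading them too thinly — fails: dispersal dilutes the
local density below the Allee threshold and the population collapses
(as happened to the Canada lynx restoration in the Adirondacks).  Given
that every released individual costs the same, which initial spatial
distribution of females and males restores the species at minimum total
cost?  This package answers that question for a one-dimensional habitat,
for conservation modellers and spatial ecologists.

## Model

Female and male densities f(x,t), m(x,t) (occupancies in [0,1]) obey

    ∂f/∂t = D_f ∂²f/∂x² + σ r f m (1 − f − m) − μ_f f
    ∂m/∂t = D_m ∂²m/∂x² + σ (1−r) f m (1 − f − m) − μ_m m

males encounter females by mass action, reproduction succeeds in
proportion to the unoccupied fraction 1−f−m, r is the sex ratio at birth
and μ_f, μ_m are sex-specific mortalities.  Positive equilibria exist iff
the mortality load A = μ_f/r + μ_m/(1−r) < σ/4; between extinction and
the stable persistence state sits an unstable Allee equilibrium, making
restoration an all-or-nothing threshold problem.  With r = 1/2 and equal
rates the system reduces *exactly* to the scalar bistable equation
u_t = D u_xx + (σ/2)u²(1−2u) − μu.

The restoration cost is the number of individuals released,
C = ∫ (f + m) dx at t = 0.  The library minimizes C subject to assured
restoration with three procedures:

1. **Aperiodic critical nucleus** — the localized unstable stationary
   profile of the single-sex model, built from the phase-plane first
   integral E = (D/2)(u′)² + G(u) along the homoclinic orbit E = 0;
2. **Rectangular clusters** — binary-search critical lengths/densities,
   with equal or sex-specific cluster lengths (descent on the female
   length with a nested male-length search);
3. **Simulated annealing** — free sex-specific shapes, every Metropolis
   proposal verified by full PDE integration.

Closed-form results exposed alongside: the fixed points, the stability
conditions, and the density-maximizing sex ratio
r* = √μ_f / (√μ_f + √μ_m).

## Worked example

```python
from reintro import CANONICAL, equilibria, critical_length, aperiodic_profile

eq = equilibria(CANONICAL)           # r=1/2, mu=0.05, D=1, sigma=1
print(eq.allee_total, eq.persistence_total)
# 0.27639320225002106 0.7236067977499789

res = critical_length(CANONICAL)     # binary search over PDE outcomes
print(res.value)
# 11.59960263328016

prof = aperiodic_profile(CANONICAL.to_single_sex())
print(prof.cost)
# 10.268767412258883
```

A rectangular release at the persistence densities (total 0.7236) must
span ≈ 11.6 length units (≈ 2.6 diffusion lengths √(D/μ)), for an assured
cost of ≈ 8.49 individuals·density — noticeably cheaper than the analytic
nucleus (≈ 10.27), whose shallow exponential tails carry extra mass.
Annealing improves the rectangle by only ~2 % at the optimal sex ratio
(run `python examples/compare_costs.py` to reproduce the ranked table).

The `examples/` directory holds one short narrative script per
capability; the `restore` console command exposes the same operations
from the shell (`restore --help`).

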