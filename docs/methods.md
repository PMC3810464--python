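# Methods

## Model and assumptions

The package models a dioecious species reintroduced into a one-dimensional
habitat.  Both sexes disperse by homogeneous diffusion; mating is
mass-action (random encounters, appropriate for animals with individual
home ranges or wind/randomly pollinated dioecious plants); the fraction of
matings that produce offspring equals the unoccupied fraction of the
environment, so growth is self-regulated with carrying capacity 1 in
occupancy units.  Mortality is density-independent and sex-specific:

    f_t = D_f f_xx + σ r f m (1 − f − m) − μ_f f
    m_t = D_m m_xx + σ (1−r) f m (1 − f − m) − μ_m m

The bilinear birth term vanishes when either sex is rare, which produces a
strong Allee effect: for mortality load A = μ_f/r + μ_m/(1−r) < σ/4 the
vacant-fraction equation s(1−s) = A/σ has two roots, mapping to an
unstable (Allee) and a stable (persistence) positive equilibrium
(f\*, m\*) = (μ_m/((1−r)σs), μ_f/(rσs)).  Stability labels are computed
from numerical Jacobian eigenvalues (central differences, step 1e−7)
rather than hand-derived formulas, so they remain correct if the rate
functions are modified.  The persistence density 1−s decreases with A, so
the density-maximizing sex ratio is the minimizer of A,
r\* = √μ_f/(√μ_f+√μ_m); the package validates this closed form against a
grid-search argmax in its tests.

σ scales the birth term and defaults to 1, which fixes the unit of time;
μ are rates per unit time (canonical default 0.05, i.e. a mean lifespan of
20 time units); D is length²/time with the diffusion length √(D/μ)
(≈ 4.47 for the defaults) the natural spatial scale.  Densities are
dimensionless occupancies; costs are density × length (individuals, up to
the per-capitum cost constant).

With r = 1/2, μ_f = μ_m and D_f = D_m, identical initial data for the
sexes evolve identically and the system reduces to
u_t = D u_xx + (σ/2)u²(1−2u) − μu.  The two integrators share the exact
floating-point expression ordering for the reaction term, so the
reduction holds bit-for-bit in the code — the cross-check in the tests
asserts a max-norm trajectory difference of 0.

## Stationary profiles and the critical nucleus

Stationary single-sex profiles solve D u″ + g(u) = 0 and conserve
E = (D/2)(u′)² + G(u) with G(u) = σu³/6 − σu⁴/4 − μu²/2.  The local
equilibria 0 and u₊ are saddles of the (u, u′) phase plane, the Allee
density u₋ a center.  Orbit periods are computed by Gauss–Kronrod
quadrature after the substitution u = c + a·sinθ, which removes the
turning-point square-root singularities analytically; near the turning
points the integrand uses the linearized limit h(u_i) = ∓g(u_i)/(u₂−u₁)
to avoid catastrophic cancellation.  Two limits are exposed because they
are scientifically meaningful: the small-amplitude period tends to the
harmonic value 2π√(D/g′(u₋)) — not zero — and the period diverges
logarithmically toward the separatrix.  Because the divergence is only
logarithmic in E_sep − E, double precision caps the observable
period-to-harmonic ratio at roughly 5–6; the tests therefore assert
monotone, non-decaying growth per decade rather than an arbitrary large
ratio.

The aperiodic critical nucleus is the homoclinic orbit at E = 0.  It
exists only in the *spreading regime* G(u₊) > 0; the boundary (the
Maxwell point, where fronts between extinction and persistence stall) is
always computed numerically by root-finding on G(u₊), never hard-coded.
In the band between the Maxwell point and the bistability fold,
equilibria exist but fronts recede and no finite introduction succeeds —
the PDE tests exhibit this directly.  The profile itself is integrated
outward from the peak u_max (the root of G on (u₋, u₊), found by
bisection to 1e−15) with DOP853 at rtol 1e−12; the square-root degeneracy
at the peak is regularized by a fourth-order series step.  The profile is
truncated at a density threshold (default 1e−3, configurable), resampled
on a uniform grid, and its cost reported as twice the trapezoidal area
(both sexes), with and without the analytic exponential-tail estimate
2·u_thr·√(D/μ) per side.  A fourth-order five-point stencil is used for
the residual diagnostic so that discretization error does not mask solver
error.

## PDE integration

Space: second-order three-point Laplacian on a uniform grid.  Boundary
conditions are not dictated by the large-habitat premise, so the default
is no-flux (reflection ghost nodes) with the habitat sized ≥ 6× the
initial support or search bound so boundaries never influence the
outcome; absorbing boundaries are available.  Time: explicit Euler with
dt = min(0.2·dx²/(2 max D), 0.1/(σ + max μ)) unless overridden — the
first term is the diffusive CFL bound with a conservative safety factor,
the second caps the reaction stiffness.  Negative round-off values are
clipped to zero; f + m ≤ 1 is validated on initial conditions only, since
the dynamics itself is attracted into the simplex and mid-run clipping
would alter the scheme.

Integration stops when the max-norm time derivative falls below
tol_converge (default 1e−8, far below all dynamical scales; criticality
searches use 1e−6), and the final state is classified by its mean total
density: within 10 % of the persistence total → persistence, below 1e−4 →
extinction.  Both thresholds are configurable decisions; any band
separating the bistable attractors gives the same classifications.  Two
early exits shortcut decided runs without touching the scheme: a peak
total density below 1e−4 (collapse is irreversible), and a total mass
that has grown past every localized critical structure
(persistence-density mass over the initial support plus eight diffusion
lengths, also ≥ 1.5× the initial mass) while the peak sits on the
persistence plateau — in the spreading regime such a state has advancing
fronts and can only fill the habitat.  Runs that reach the time cap are
labelled NOT_CONVERGED and treated as failed restorations (with a
warning) by the searches, which biases critical lengths conservatively
upward by at most the search resolution.

## Criticality searches

Rectangular initial conditions place each sex at a homogeneous density in
a centered cluster; the two edge cells carry fractional weights so the
discrete mass equals density × length exactly and criticality varies
continuously in L, letting the binary search resolve below one grid
spacing when asked.  The critical length search doubles an upper bound
from one diffusion length until persistence (capped at 50 diffusion
lengths, beyond which DivergentSearch signals sub-threshold densities or
the non-spreading regime), fixes the habitat at 6× that bound, and
bisects.  Default grid spacing is √(max D/min μ)/16, and default initial
densities are the persistence-equilibrium densities — the density scans
show the cost minimum lies only a few percent below them, so they are the
natural operating point.  Bisection assumes the outcome is monotone in
cluster length; for the scalar model this is the parabolic comparison
principle (tested), for the two-sex system it is verified empirically by
re-simulating the final bracket endpoints.

The critical density search bisects the total density at fixed length,
splitting it between the sexes in the persistence proportion by default;
its lower bound, the Allee total, is taken as failing on the homogeneous-
limit argument rather than simulated.

Reported "assured" costs use the feasible upper end of the final bracket
(the smallest length demonstrated to restore), not the bracket midpoint;
the marginally unstable nucleus is likewise inflated by 2 % when used as
a reported initial condition, so every reported state re-simulates to
persistence.

In the diffusion-scaling study the grid spacing tracks √D so the relative
resolution is constant; the x → √c·x continuum symmetry then holds
exactly on the discrete problem, and the fitted exponent isolates the
dynamics rather than quantization bias.  With only one sex's coefficient
varied, the √D law is an asymptotic statement: it emerges when the varied
coefficient dominates the fixed one (measured slope ≈ 0.53 for D_m ∈
[1, 16] against D_f = 0.25) and flattens in the opposite limit (slope
≈ 0.25 over a range symmetric about the fixed value), which the scan API
leaves to the caller to configure.

## Sex-specific cluster lengths

For fixed female length L_f, a nested binary search gives the critical
male length L_m(L_f) and hence a one-dimensional cost
C(L_f) = n_f L_f + n_m L_m(L_f).  The descent moves L_f by one grid unit
per step — continuing through zero local differences, which are
discretization plateaus — and stops after the cost has exceeded the best
visited value on three consecutive moves, returning the best point.  The
direction is chosen by probing both neighbours at the start.  The inner
searches may use a resolution finer than the descent step (fractional
edges make lengths continuous); this keeps the cost ratio
R = C_unequal/C_equal measurable to a few tenths of a percent without
shrinking the step.  Convexity of C is relied on, as the descent has no
escape mechanism; a rise-then-fall pattern in the trace beyond the
discretization quantum is detected and flagged.  Consecutive searches are
warm-started from the previous L_m, since the critical male length moves
by O(step).

## Simulated annealing

Shapes are free non-negative vectors per sex on the PDE grid.  Moves
(probabilities 0.8/0.1/0.1): perturb one site of one sex by
uniform(−a, a) clipped to [0, 1−other]; extend the sex's support by one
cell at a random edge with seed density uniform(0, a); zero a random edge
cell.  A proposal is first screened by the Metropolis rule
min(1, exp(−ΔC/T)) on its cost — cost changes are known analytically — and
only candidates surviving the screen are integrated to verify the
restoration constraint; infeasible candidates are rejected (default),
keeping the chain in the feasible region, or carried with a fixed large
cost penalty under the alternative policy.  The ordering (cost screen
before feasibility) only skips integrations for proposals that would be
rejected regardless of feasibility, so the visited distribution is
unchanged while uphill-rejection integrations are saved.  T₀ defaults to
the standard deviation of the cost change over 100 random proposals;
cooling is geometric at 0.95 per stage, 200 proposals per stage, stopping
below 1 % acceptance or at the stage cap.  The schedule is a declared
decision: the scientific claims rest on cost ordering (best-visited
feasible ≤ initial rectangular cost, equality up to a few percent at r\*),
not on any particular schedule, and the chain claims best-visited, not
global, optimality.  The best state is re-verified by a fresh integration
before being returned.

## Problem sizes and defaults used in tests and the acceptance script

PDE-heavy studies run at grid spacing √(D/μ)/12 (≈ 0.37 length units for
the canonical set), giving habitats of 250–700 nodes; annealing runs use
12–15 stages of 30–40 moves on the search grid.  These sizes keep each
study at seconds to about a minute while the grid-refinement test pins
the critical length within 2 % of a 2× finer grid.  The canonical
parameter set (r = 1/2, μ = 0.05, D = 1, σ = 1) sits well inside the
spreading regime (Maxwell point at μ = σ/18 ≈ 0.0556, bistability fold at
σ/16); sex-ratio studies use biases up to |r − r\*| ≈ 0.1, inside the
spreading band of the canonical mortalities.

## What the generated scenarios do and do not show

All inputs are synthetic by construction — the model's own parameter
space is the study object, and the fixture sweeps only filter parameter
sets by the existence condition.  Passing tests therefore demonstrate the
internal consistency of the model and its optimization machinery
(reduction exactness, closed forms vs independent numerics, scaling
symmetries, method ordering), not agreement with field data: real
reintroductions involve demographic stochasticity, non-diffusive and
heavy-tailed dispersal, mating systems beyond mass action, interspecific
interactions and two-dimensional habitats with front curvature, none of
which are modelled here.

## Known limitations

* Explicit Euler is the only integrator; stiff or strongly
  advection-dominated extensions would need a different scheme.
* Outcome classification near the Maxwell point is slow (fronts stall);
  searches there may return NOT_CONVERGED-driven conservative answers.
* The unequal-cluster descent assumes convexity; it flags but does not
  recover from non-convex cost traces.
* The annealing move set never proposes translations, so optima are
  reported up to the initial centering.
* The log-divergence of orbit periods near the separatrix is resolvable
  only down to E-gaps of ~1e−14 of the center value in double precision.
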