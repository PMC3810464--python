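"""Critical rectangular cluster size and the sqrt-D scaling law.

For a rectangular introduction at the persistence-equilibrium densities
there is a smallest cluster length that restores the population; it
scales as the square root of the diffusion coefficient.
"""

from dataclasses import replace

from reintro import CANONICAL, critical_length, equilibria, scaling_exponent

eq = equilibria(CANONICAL)
res = critical_length(CANONICAL)
total = eq.persistence_total
print(f"critical equal-cluster length L_c = {res.value:.3f} "
      f"(bracket {res.bracket[0]:.3f}..{res.bracket[1]:.3f}, {res.evaluations} PDE runs)")
print(f"minimum assured rectangular cost = (n_f + n_m) * L = {total * res.bracket[1]:.4f}")

res4 = critical_length(replace(CANONICAL, D_f=4.0, D_m=4.0))
print(f"\nquadrupling both diffusion coefficients: L_c = {res4.value:.3f} "
      f"(ratio {res4.value / res.value:.3f}, expected 2 from the x -> sqrt(c) x symmetry)")

slope, table = scaling_exponent(CANONICAL, [0.25, 0.5, 1.0, 2.0, 4.0])
print(f"log-log slope of L_c vs D over {list(table['D'])}: {slope:.3f} (sqrt law: 0.5)")
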