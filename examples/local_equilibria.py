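"""Fixed points of the local two-sex dynamics and the optimal sex ratio.

The local model is df/dt = sigma r f m (1-f-m) - mu_f f,
dm/dt = sigma (1-r) f m (1-f-m) - mu_m m.  When the mortality load
A = mu_f/r + mu_m/(1-r) is below sigma/4, two positive equilibria exist:
an unstable Allee point and a stable persistence point.
"""

from reintro import ModelParams, equilibria, optimal_sex_ratio, admissible_sex_ratio_interval

params = ModelParams(r=0.5, mu_f=0.05, mu_m=0.05)
eq = equilibria(params)
print(f"mortality load A = {params.A:.4f} (must be < {params.sigma / 4:.4f})")
print(f"Allee point       (f, m) = ({eq.allee[0]:.6f}, {eq.allee[1]:.6f})  stable={eq.allee_stable}")
print(f"persistence point (f, m) = ({eq.persistence[0]:.6f}, {eq.persistence[1]:.6f})  stable={eq.persistence_stable}")
print(f"total densities: Allee {eq.allee_total:.6f} < persistence {eq.persistence_total:.6f}")

# with unequal mortalities the density-maximizing sex ratio shifts toward
# producing more of the high-mortality sex
mu_f, mu_m = 0.06, 0.03
r_star = optimal_sex_ratio(mu_f, mu_m)
lo, hi = admissible_sex_ratio_interval(mu_f, mu_m)
print(f"\nmu_f={mu_f}, mu_m={mu_m}: optimal sex ratio r* = {r_star:.4f}")
print(f"admissible sex ratios (positive equilibria exist): ({lo:.4f}, {hi:.4f})")
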